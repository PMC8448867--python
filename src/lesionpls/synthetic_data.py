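"""Synthetic stroke cohorts with the statistical structure the analysis assumes.

No patient data ship with the package, so every stage of the pipeline is
exercised on generated cohorts that emulate the salient structure of a
lesion-symptom treatment study:

* a toy atlas: a small 3-D grid partitioned into contiguous regions
  (Voronoi cells of random seed points), optionally with overlapping
  duplicate regions from a "second atlas";
* lesions: contiguous stochastic-growth blobs confined to one half of the
  grid (the "territory", standing in for the left hemisphere), so that
  territory-external regions are never damaged and are pruned during
  encoding, and loads of neighbouring regions are strongly correlated while
  loads of regions at opposite ends of the territory anticorrelate (damage
  here implies sparing there) — the covariance that produces proxy-region
  weights;
* responses: a planted linear map of region loads (a cluster of "harmful"
  regions with negative weights) plus a therapy-hours term, an optional
  hours × lesion interaction, and Gaussian noise whose sd defaults to 10% of
  the noiseless signal's sd;
* nuisance blocks: demographics independent of the response, an initial
  severity score and a behavioural battery that are noisy mixtures of lesion
  loads (collinear with the lesion block but carrying no extra signal).

Everything is reproducible from (config, seed); ground truth (planted
weights, noiseless responses, blob seeds) is returned alongside the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lesion_encoding import LesionMask, Region, RegionSet, encode_cohort
from .model_core import Cohort

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "make_toy_atlas",
    "make_lesions",
    "make_responses",
    "make_cohort",
    "region_centroids",
    "proxy_generator_config",
    "select_proxy_target",
]

SPACE_TAG = "toy-grid"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    Defaults mirror the study conditions of a small anomia treatment cohort:
    18 patients, ~40 atlas regions on a 20³ grid, therapy dose 73 ± 25 hours,
    and observation noise at 10% of the planted signal's sd
    (``noise_sd=None``).  Responses are on the trained-item-count scale
    (0–150 items) but left continuous unless ``round_response``.
    """

    n_patients: int = 18
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_regions: int = 40
    n_overlap_regions: int = 0          # duplicated (dilated) regions, "second atlas"
    territory_fraction: float = 0.5     # fraction of the x-axis lesions may occupy
    blob_size_range: tuple[int, int] = (500, 900)
    n_blobs_range: tuple[int, int] = (1, 2)
    lesion_shape: str = "walk"          # "walk" (stochastic growth) or "sphere"
    blob_seed_spread: float | None = None  # concentrate blob seeds around the territory's
                                           # long axis (sd in voxels); None → uniform
    harmful_zone_fraction: float = 0.4  # regions with centroid y below this get negative weights
    harmful_weight: float = -40.0       # response points lost if a harmful region is fully lesioned
    hours_mean: float = 73.0
    hours_sd: float = 25.0
    beta_hours: float = 0.4             # response points per therapy hour
    beta_interaction: float = 0.0       # optional hours × lesion coupling
    response_intercept: float = 65.0
    noise_sd: float | None = None       # None → 0.1 × sd(noiseless response)
    n_behavioural: int = 28
    round_response: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_regions < 1:
            raise ValueError("counts must be positive (n_patients ≥ 2)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise sd must be ≥ 0")
        if self.n_regions > int(np.prod(self.grid_shape)):
            raise ValueError("more regions than grid voxels")
        if self.lesion_shape not in ("walk", "sphere"):
            raise ValueError("lesion_shape must be 'walk' or 'sphere'")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth behind it."""

    cohort: Cohort
    atlas: RegionSet
    loads: "pd.DataFrame"
    planted_weights: pd.Series        # per retained region, response points at full load
    noiseless_response: np.ndarray
    blob_seeds: tuple[tuple[int, int, int], ...]
    dropped_region_ids: tuple[str, ...]
    config: GeneratorConfig


def _grid_coords(shape) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    return idx.astype(float)


def make_toy_atlas(config: GeneratorConfig) -> RegionSet:
    """Partition the grid into contiguous regions: Voronoi cells of seeded points.

    Deterministic given ``config.seed``.  With ``n_overlap_regions`` > 0, the
    first few regions are duplicated in dilated form under a second atlas id,
    exercising the overlap-retention rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    shape = config.grid_shape
    n_vox = int(np.prod(shape))
    coords = _grid_coords(shape)
    seed_idx = rng.choice(n_vox, size=config.n_regions, replace=False)
    seeds = coords[seed_idx]
    # nearest seed per voxel; ties broken by lowest region index (argmin)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    owner = d2.argmin(axis=1)
    regions = []
    width = len(str(config.n_regions))
    for r in range(config.n_regions):
        membership = (owner == r).reshape(shape)
        regions.append(Region(f"R{r:0{width}d}", "toy-a", membership))
    if config.n_overlap_regions:
        from scipy.ndimage import binary_dilation

        for r in range(min(config.n_overlap_regions, config.n_regions)):
            dilated = binary_dilation(regions[r].membership, iterations=1)
            regions.append(Region(f"R{r:0{width}d}-b", "toy-b", dilated))
    return RegionSet(tuple(regions), space_tag=SPACE_TAG)


_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_blob(rng: np.random.Generator, start: tuple[int, int, int],
               target_size: int, allowed: np.ndarray) -> np.ndarray:
    """Contiguous blob by stochastic boundary growth inside an allowed mask."""
    blob = np.zeros(allowed.shape, dtype=bool)
    blob[start] = True
    frontier: list[tuple[int, int, int]] = []

    def push_neighbours(v):
        for dv in _NEIGHBOURS:
            w = (v[0] + dv[0], v[1] + dv[1], v[2] + dv[2])
            if all(0 <= w[i] < allowed.shape[i] for i in range(3)):
                if allowed[w] and not blob[w]:
                    frontier.append(w)

    push_neighbours(start)
    size = 1
    while size < target_size and frontier:
        i = rng.integers(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        if blob[v]:
            continue
        blob[v] = True
        size += 1
        push_neighbours(v)
    return blob


def _sphere_blob(start, target_size, allowed) -> np.ndarray:
    coords = _grid_coords(allowed.shape)
    d2 = ((coords - np.asarray(start, float)) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    flat_allowed = allowed.ravel()
    blob = np.zeros(flat_allowed.shape, dtype=bool)
    taken = 0
    for i in order:
        if flat_allowed[i]:
            blob[i] = True
            taken += 1
            if taken >= target_size:
                break
    return blob.reshape(allowed.shape)


def territory_mask(config: GeneratorConfig) -> np.ndarray:
    """Sub-volume lesions are confined to (the 'left hemisphere' of the toy grid)."""
    shape = config.grid_shape
    cutoff = int(round(shape[0] * config.territory_fraction))
    mask = np.zeros(shape, dtype=bool)
    mask[:cutoff] = True
    return mask


def make_lesions(config: GeneratorConfig, atlas: RegionSet | None = None
                 ) -> tuple[list[LesionMask], tuple[tuple[int, int, int], ...]]:
    """One lesion mask per patient: a union of contiguous blobs in the territory.

    Blob seed voxels are uniform over the territory by default, so lesion
    position varies across patients; with roughly constant total lesion
    volume this yields positively correlated loads in neighbouring regions
    and anticorrelated loads at opposite ends of the territory.  With
    ``blob_seed_spread`` set, seeds are instead concentrated around the
    territory's long (y) axis — emulating a cohort of strokes in one
    vascular territory whose lesions vary chiefly along a single
    anterior–posterior gradient, the covariance that makes one spared
    region a clean proxy for damage elsewhere.  Returns the masks and the
    primary blob seed of each patient.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    allowed = territory_mask(config)
    allowed_idx = np.argwhere(allowed)
    sx, sy, sz = config.grid_shape
    x_max = max(int(round(sx * config.territory_fraction)), 1)
    masks, primary_seeds = [], []
    lo, hi = config.blob_size_range
    for p in range(config.n_patients):
        grid = np.zeros(config.grid_shape, dtype=bool)
        n_blobs = int(rng.integers(config.n_blobs_range[0], config.n_blobs_range[1] + 1))
        first_seed = None
        for b in range(n_blobs):
            size = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            if config.blob_seed_spread is None:
                start = tuple(allowed_idx[rng.integers(len(allowed_idx))])
            else:
                s = config.blob_seed_spread
                start = (
                    int(np.clip(round(rng.normal(x_max / 2, s)), 0, x_max - 1)),
                    int(rng.integers(0, sy)),
                    int(np.clip(round(rng.normal(sz / 2, s)), 0, sz - 1)),
                )
            if first_seed is None:
                first_seed = start
            if size <= 0:
                continue
            if config.lesion_shape == "walk":
                grid |= _grow_blob(rng, start, size, allowed)
            else:
                grid |= _sphere_blob(start, size, allowed)
        masks.append(LesionMask(patient_id=f"P{p:02d}",
                                voxel_grid=grid.astype(np.uint8),
                                space_tag=SPACE_TAG))
        primary_seeds.append(tuple(int(c) for c in first_seed))
    return masks, tuple(primary_seeds)


def region_centroids(atlas: RegionSet) -> pd.DataFrame:
    """Voxel-centroid coordinates per region (rows follow atlas order)."""
    rows = []
    for r in atlas:
        c = np.argwhere(r.membership).mean(axis=0)
        rows.append({"region_id": r.region_id, "x": c[0], "y": c[1], "z": c[2]})
    return pd.DataFrame(rows).set_index("region_id")


def plant_region_weights(config: GeneratorConfig, atlas: RegionSet,
                         region_ids: list[str]) -> pd.Series:
    """Planted response weights for the retained regions.

    Regions whose centroid lies in the 'harmful zone' (low-y end of the
    grid) receive the configured negative weight, jittered ±20%; all other
    regions carry zero weight.  Damage elsewhere then predicts a *better*
    response only through lesion covariance, never directly — the planted
    proxy structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cent = region_centroids(atlas)
    y_cut = atlas.shape[1] * config.harmful_zone_fraction
    weights = {}
    for rid in region_ids:
        if cent.loc[rid, "y"] < y_cut:
            weights[rid] = config.harmful_weight * rng.uniform(0.8, 1.2)
        else:
            weights[rid] = 0.0
    return pd.Series(weights, name="planted_weight").loc[region_ids]


def make_responses(config: GeneratorConfig, loads: pd.DataFrame, hours: np.ndarray,
                   planted: pd.Series) -> tuple[np.ndarray, np.ndarray, float]:
    """Responses from the planted linear model plus noise.

    y = intercept + Σ_r w_r · load_r + β_h · hours
        + β_int · hours · Σ_r w_r · load_r + ε,   ε ~ N(0, noise_sd²)

    with noise_sd defaulting to 10% of the noiseless response's sd.  Returns
    (response, noiseless response, noise sd used).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lesion_term = loads.loc[:, planted.index].to_numpy(float) @ planted.to_numpy()
    noiseless = (
        config.response_intercept
        + lesion_term
        + config.beta_hours * hours
        + config.beta_interaction * hours * lesion_term
    )
    sd = config.noise_sd
    if sd is None:
        sd = 0.1 * float(np.std(noiseless, ddof=1))
    y = noiseless + rng.normal(0.0, sd, size=len(noiseless)) if sd > 0 else noiseless.copy()
    if config.round_response:
        y = np.round(y)
    return y, noiseless, float(sd)


def make_cohort(config: GeneratorConfig | None = None, seed: int | None = None
                ) -> SyntheticCohort:
    """Generate a full synthetic cohort: atlas, lesions, all predictor blocks, response."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    atlas = make_toy_atlas(config)
    masks, blob_seeds = make_lesions(config, atlas)
    load_matrix = encode_cohort(masks, atlas, drop_zero_variance=True)
    loads = load_matrix.to_dataframe().reset_index(drop=True)
    patient_ids = load_matrix.patient_ids
    n = config.n_patients

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    hours = np.clip(rng.normal(config.hours_mean, config.hours_sd, size=n), 1.0, None)

    demographics = pd.DataFrame({
        "age_at_onset": rng.normal(60.0, 12.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "months_post_stroke": 6.0 + rng.exponential(36.0, size=n),
    })

    total_load = loads.to_numpy().mean(axis=1)
    initial = pd.DataFrame({
        "initial_naming_accuracy": np.clip(
            np.round(105.0 - 90.0 * total_load + rng.normal(0.0, 15.0, size=n)),
            0.0, 150.0,
        )
    })

    mixing = rng.normal(0.0, 1.0, size=(loads.shape[1], config.n_behavioural))
    behavioural_raw = loads.to_numpy() @ mixing
    behavioural_raw += rng.normal(0.0, 0.5 * behavioural_raw.std(ddof=1) + 1e-9,
                                  size=behavioural_raw.shape)
    behavioural = pd.DataFrame(
        behavioural_raw,
        columns=[f"assessment_{i:02d}" for i in range(config.n_behavioural)],
    )

    planted = plant_region_weights(config, atlas, list(loads.columns))
    y, noiseless, _sd = make_responses(config, loads, hours, planted)

    cohort = Cohort(
        patient_ids=patient_ids,
        blocks={
            "demographics": demographics,
            "initial": initial,
            "hours": pd.DataFrame({"therapy_hours": hours}),
            "behavioural": behavioural,
            "lesions": loads,
        },
        response=y,
    )
    return SyntheticCohort(
        cohort=cohort,
        atlas=atlas,
        loads=loads,
        planted_weights=planted,
        noiseless_response=noiseless,
        blob_seeds=blob_seeds,
        dropped_region_ids=load_matrix.dropped_region_ids,
        config=config,
    )


def proxy_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Generator preset with a pronounced spared-region proxy structure.

    Single-blob lesions of near-constant volume, seeded along the
    territory's long axis on a finer (60-region) parcellation, so lesion
    covariance is dominated by one anterior–posterior position gradient:
    damage at one end of the territory strongly implies sparing at the
    other.  Under this configuration a spared region's pairwise load
    correlations closely track the model's perturbation weights.
    """
    params = dict(
        n_regions=60,
        n_blobs_range=(1, 1),
        blob_size_range=(600, 700),
        blob_seed_spread=0.8,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def select_proxy_target(synthetic: SyntheticCohort, weights) -> str:
    """The designated proxy region of a synthetic cohort.

    Among regions whose load is negatively correlated with mean load over
    the ground-truth harmful regions (candidates whose damage implies
    sparing of the regions that genuinely hurt the response), returns the
    one carrying the largest perturbation weight — the synthetic analogue of
    picking the strongest positively weighted region.
    """
    loads = synthetic.loads
    w = weights.as_series()
    region_w = w[w.index.isin(loads.columns)]
    harmful = synthetic.planted_weights[synthetic.planted_weights != 0].index
    harm_load = loads[list(harmful)].mean(axis=1).to_numpy()
    candidates = [
        r for r in region_w.index
        if loads[r].std() > 0 and np.corrcoef(loads[r], harm_load)[0, 1] < 0
    ]
    if not candidates:
        candidates = list(region_w.index)
    return str(region_w[candidates].idxmax())
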