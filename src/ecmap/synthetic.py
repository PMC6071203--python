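"""Synthetic two-condition fMRI cohort with planted network structure.

The generator emulates the statistical structure the downstream analysis
assumes: each subject contributes a resting run and an n-back task run on a
common grid, voxel signals are mixtures of smooth network "blob" maps with
correlated network time courses, and three planted effects tie the data to
the scientific questions:

* a hub network whose cross-network coupling rises under task load and
  increases linearly with age;
* a sensory-like network whose cross-network coupling falls under task;
* in-scanner behavior (hits / false alarms over 45 targets and 135
  non-targets) linked to the subject's hub coupling through a logistic
  model, so working-memory sensitivity (d-prime) tracks hub centrality.

All randomness flows from ``CohortConfig.seed``; regeneration with the same
configuration is bit-identical.  :class:`GroundTruth` records everything a
recovery test needs (atlas, per-subject coupling, effect signs).
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TaskDesign, hrf_regressor, make_nback_design, CONDITION_NAMES
from .ecm import BoldRun, Mask, REST, TASK
from .errors import ConfigError, GridTooSmallError
from .task_glm import BehaviorScores, behavior_scores

logger = logging.getLogger(__name__)

HUB, SENSORY, OTHER, ARTIFACT = "hub", "sensory", "other", "artifact"

# BOLD response scales with working-memory load; the attention-only 0-back
# baseline evokes a weaker response than the 1- and 2-back conditions, which
# is what the (1-back + 2-back)/2 - 0-back contrast measures.
LOAD_WEIGHTS = {"0-back": 0.5, "1-back": 1.0, "2-back": 1.25}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the emulated study: two runs per subject at TR 3.0 s,
    ages uniform on 8-22 years, an n-back run of nine 30 s blocks with 10 s
    instruction periods (120 volumes), and a rest run of 124 volumes.
    Effect-size fields are in correlation units per unit of their driver
    (e.g. ``age_slope`` is the change in hub cross-network correlation per
    year of age).
    """

    n_subjects: int = 40
    grid_dims: tuple[int, int, int] = (20, 20, 12)
    tr_seconds: float = 3.0
    n_timepoints_rest: int = 124
    n_timepoints_task: int = 120
    k_networks: int = 6
    n_artifacts: int = 2
    noise_sd: float = 0.5
    base_coupling: float = 0.15
    hub_base_coupling: float = 0.2
    coupling_subject_sd: float = 0.03
    task_coupling_delta: float = 0.25
    delta_subject_sd: float = 0.3
    age_slope: float = 0.03
    network_strength_sd: float = 0.15
    behavior_link: float = 6.0
    hit_intercept: float = 0.5
    hit_age_slope: float = 0.05
    fa_intercept: float = -1.5
    activation_amplitude: float = 0.05
    age_range_years: tuple[float, float] = (8.0, 22.0)
    block_seconds: float = 30.0
    instruction_seconds: float = 10.0
    trial_seconds: float = 1.5
    blob_sigma: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_timepoints_rest", "n_timepoints_task", "k_networks"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_artifacts < 0:
            raise ConfigError("n_artifacts must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not self.age_range_years[0] < self.age_range_years[1]:
            raise ConfigError("age_range_years must be ordered (low, high)")
        if int(np.prod(self.grid_dims)) < 8 * self.k_networks:
            raise ConfigError("grid volume must be at least 8 x k_networks")

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range_years[0] + self.age_range_years[1])


@dataclass
class NetworkAtlas:
    """Planted spatial layout: nonnegative unit-peak blob maps plus roles.

    Labels are ``hub`` (task-positive, age-modulated), ``sensory``
    (task-negative), ``other`` (weakly task-modulated filler networks), and
    ``artifact`` (structured nuisance sources a decomposition should
    discard).
    """

    maps: np.ndarray  # (k_total, x, y, z), nonnegative, unit peak
    labels: list[str]
    sigma: float = 1.5

    @property
    def k_total(self) -> int:
        return self.maps.shape[0]

    @property
    def signal_indices(self) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab != ARTIFACT])

    @property
    def artifact_indices(self) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab == ARTIFACT])

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def flat_maps(self, mask: Mask) -> np.ndarray:
        """(k_total, V) maps restricted to the mask."""
        return self.maps[:, mask.array]


@dataclass
class SubjectRecord:
    """One simulated participant.

    ``hub_coupling`` is the subject's latent hub cross-network correlation
    in the task state (the quantity behavior is tied to);
    ``rest_coupling`` is the same latent in the resting state.
    """

    id: str
    age_years: float
    sex: int
    hub_coupling: float
    rest_coupling: float | None = None
    # stable individual differences in network expression amplitude
    network_strengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ConfigError("sex must be coded 0/1")


@dataclass
class GroundTruth:
    """Everything needed to verify recovery of the planted structure."""

    atlas: NetworkAtlas
    mask: Mask
    config: CohortConfig
    subjects: list[SubjectRecord]
    design: TaskDesign
    activation_amplitudes: np.ndarray  # per network, task-regressor amplitude
    coupling_deltas: np.ndarray  # per network, task-state cross-coupling change
    age_slopes: np.ndarray  # per network, coupling change per year

    def expected_correlation(self, subject: SubjectRecord, condition: str) -> np.ndarray:
        return _network_correlation(subject, condition, self.atlas, self.config)

    @property
    def task_effect_signs(self) -> np.ndarray:
        return np.sign(self.coupling_deltas)


def role_labels(k_networks: int, n_artifacts: int = 0) -> list[str]:
    """Deterministic role assignment: network 0 is the hub, network 1 (if
    present) is sensory-like, the rest are filler; artifacts come last."""
    labels = [HUB]
    if k_networks >= 2:
        labels.append(SENSORY)
    labels.extend([OTHER] * (k_networks - len(labels)))
    labels.extend([ARTIFACT] * n_artifacts)
    return labels


def default_mask(grid_dims: tuple[int, int, int]) -> Mask:
    """Ellipsoidal analysis mask inscribed in the grid (~half its volume)."""
    nx, ny, nz = grid_dims
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (
        ((x - cx) / (nx / 2)) ** 2
        + ((y - cy) / (ny / 2)) ** 2
        + ((z - cz) / (nz / 2)) ** 2
    )
    return Mask(r <= 1.0)


def _blob(grid_dims: tuple[int, int, int], center: np.ndarray, sigma: float) -> np.ndarray:
    nx, ny, nz = grid_dims
    x, y, z = np.ogrid[:nx, :ny, :nz]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def generate_network_maps(
    grid_dims: tuple[int, int, int],
    k_networks: int,
    seed: int,
    n_artifacts: int = 0,
    sigma: float = 1.5,
    max_restarts: int = 50,
) -> NetworkAtlas:
    """Place k smooth nonnegative unit-peak blobs with low spatial overlap.

    Centers are drawn inside the default ellipsoidal mask with a minimum
    pairwise separation; placements whose maps correlate at >= 0.5 are
    rejected and redrawn.  Deterministic given ``seed``.
    """
    k_total = k_networks + n_artifacts
    mask = default_mask(grid_dims)
    margin = max(1.0, 1.3 * sigma)
    lo = np.array([margin] * 3)
    hi = np.array(grid_dims) - 1 - margin
    if np.any(hi <= lo):
        raise GridTooSmallError(f"grid {grid_dims} too small for blobs of sigma {sigma}")
    min_sep = 2.4 * sigma
    rng = np.random.default_rng(seed)
    center_grid = np.array([(d - 1) / 2 for d in grid_dims])
    semi = np.array([d / 2 for d in grid_dims])

    for _ in range(max_restarts):
        centers: list[np.ndarray] = []
        attempts = 0
        while len(centers) < k_total and attempts < 400 * k_total:
            attempts += 1
            c = rng.uniform(lo, hi)
            if np.sum(((c - center_grid) / (0.85 * semi)) ** 2) > 1.0:
                continue
            if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                centers.append(c)
        if len(centers) < k_total:
            continue
        maps = np.stack([_blob(grid_dims, c, sigma) for c in centers])
        maps /= maps.max(axis=(1, 2, 3), keepdims=True)  # unit peak on the lattice
        flat = maps[:, mask.array]
        if k_total > 1:
            corr = np.corrcoef(flat)
            off = corr[~np.eye(k_total, dtype=bool)]
            if np.any(np.abs(off) >= 0.5):
                continue
        supra = (flat >= 0.5).sum(axis=1)
        if np.any(supra < 8):
            continue
        return NetworkAtlas(
            maps=maps, labels=role_labels(k_networks, n_artifacts), sigma=sigma
        )
    raise GridTooSmallError(
        f"could not place {k_total} networks on grid {grid_dims} "
        f"(sigma {sigma}, min separation {min_sep:.1f})"
    )


def _run_rng(config: CohortConfig, subject_id: str, stream: int) -> np.random.Generator:
    """Independent, reproducible RNG stream per (cohort, subject, purpose)."""
    tag = zlib.crc32(subject_id.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag, stream]))


def _psd_correlation(R: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest-ish PSD correlation matrix."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= 1e-8:
        return R
    vals = np.clip(vals, 1e-8, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def _network_correlation(
    subject: SubjectRecord, condition: str, atlas: NetworkAtlas, config: CohortConfig
) -> np.ndarray:
    """Planted network time-course correlation matrix for one run.

    Signal networks share a weak baseline coupling; the hub row is set to
    the subject's condition-specific latent coupling, the sensory row drops
    under task, and artifact sources stay uncorrelated with everything.
    """
    k = atlas.k_total
    labels = atlas.labels
    R = np.eye(k)
    sig = [i for i in range(k) if labels[i] != ARTIFACT]
    for a in sig:
        for b in sig:
            if a != b:
                R[a, b] = config.base_coupling
    if HUB in labels:
        h = atlas.index_of(HUB)
        if condition == TASK:
            c = subject.hub_coupling
        else:
            c = (
                subject.rest_coupling
                if subject.rest_coupling is not None
                else subject.hub_coupling - config.task_coupling_delta
            )
        c = float(np.clip(c, -0.85, 0.85))
        for b in sig:
            if b != h:
                R[h, b] = R[b, h] = c
    if SENSORY in labels and condition == TASK:
        # sensory suppression under task takes precedence on every sensory
        # pair, including hub-sensory: task engagement decouples the sensory
        # network from the rest of the graph
        s = atlas.index_of(SENSORY)
        c = float(np.clip(config.base_coupling - config.task_coupling_delta, -0.85, 0.85))
        for b in sig:
            if b != s:
                R[s, b] = R[b, s] = c
    return _psd_correlation(R)


def activation_amplitudes(atlas: NetworkAtlas, config: CohortConfig) -> np.ndarray:
    """Per-network amplitude of the HRF-convolved task-engagement regressor.

    The hub activates, the sensory network deactivates, filler networks get
    weak alternating-sign responses, artifacts none — so task-evoked
    activation co-varies with the planted centrality changes across
    networks.
    """
    amp = np.zeros(atlas.k_total)
    other_rank = 0
    for i, lab in enumerate(atlas.labels):
        if lab == HUB:
            amp[i] = config.activation_amplitude
        elif lab == SENSORY:
            amp[i] = -config.activation_amplitude
        elif lab == OTHER:
            amp[i] = (0.4 if other_rank % 2 == 0 else -0.4) * config.activation_amplitude
            other_rank += 1
    return amp


def coupling_deltas(atlas: NetworkAtlas, config: CohortConfig) -> np.ndarray:
    delta = np.zeros(atlas.k_total)
    for i, lab in enumerate(atlas.labels):
        if lab == HUB:
            delta[i] = config.task_coupling_delta
        elif lab == SENSORY:
            delta[i] = -config.task_coupling_delta
    return delta


def network_age_slopes(atlas: NetworkAtlas, config: CohortConfig) -> np.ndarray:
    slopes = np.zeros(atlas.k_total)
    if HUB in atlas.labels:
        slopes[atlas.index_of(HUB)] = config.age_slope
    return slopes


def simulate_run(
    subject: SubjectRecord,
    condition: str,
    atlas: NetworkAtlas,
    design: TaskDesign | None,
    config: CohortConfig,
    mask: Mask | None = None,
) -> BoldRun:
    """Simulate one 4D run as noisy mixtures of network time courses.

    Voxel series are ``sum_k map_k(v) s_k(t)`` plus i.i.d. Gaussian noise,
    with network courses drawn from the planted condition- and
    age-dependent correlation structure.  Task runs additionally add the
    HRF-convolved block regressor scaled by each network's activation
    amplitude.  ``design`` must be provided iff ``condition == 'task'``.
    """
    if (condition == TASK) != (design is not None):
        raise ConfigError("design must be provided exactly for task runs")
    mask = mask or default_mask(config.grid_dims)
    T = config.n_timepoints_task if condition == TASK else config.n_timepoints_rest
    rng = _run_rng(config, subject.id, 0 if condition == REST else 1)

    R = _network_correlation(subject, condition, atlas, config)
    L = np.linalg.cholesky(R)
    courses = L @ rng.standard_normal((atlas.k_total, T))
    if subject.network_strengths is not None:
        strengths = np.asarray(subject.network_strengths, dtype=float)
        if strengths.shape != (atlas.k_total,):
            raise ConfigError(
                f"network_strengths has shape {strengths.shape}, expected "
                f"({atlas.k_total},)"
            )
        courses = strengths[:, None] * courses

    if condition == TASK:
        engagement = np.zeros(T)
        for name in CONDITION_NAMES:
            engagement += LOAD_WEIGHTS[name] * hrf_regressor(
                design.condition_onsets[name], T, config.tr_seconds
            )
        amp = activation_amplitudes(atlas, config)
        courses = courses + amp[:, None] * engagement[None, :]

    flat_maps = atlas.flat_maps(mask)  # (k, V)
    signal = flat_maps.T @ courses  # (V, T)
    noise = rng.standard_normal(signal.shape) * config.noise_sd
    data = np.zeros(config.grid_dims + (T,))
    data[mask.array] = signal + noise
    return BoldRun(
        data=data,
        tr_seconds=config.tr_seconds,
        subject_id=subject.id,
        condition=condition,
    )


def simulate_behavior(subject: SubjectRecord, config: CohortConfig) -> BehaviorScores:
    """Draw in-scanner hit / false-alarm counts tied to hub coupling.

    ``logit(p_hit) = a + b (age - midpoint) + c (hub_coupling - mean)``
    with ``a = hit_intercept``, ``b = hit_age_slope``, ``c = behavior_link``;
    false alarms use a decreasing logit with half-strength slopes.  Counts
    are binomial over the paradigm's 45 targets and 135 non-targets.
    """
    rng = _run_rng(config, subject.id, 2)
    age_c = subject.age_years - config.age_midpoint
    coupling_c = subject.hub_coupling - (
        config.hub_base_coupling + config.task_coupling_delta
    )
    n_targets, n_nontargets = 45, 135
    p_hit = _expit(config.hit_intercept + config.hit_age_slope * age_c
                   + config.behavior_link * coupling_c)
    p_fa = _expit(config.fa_intercept - 0.5 * config.hit_age_slope * age_c
                  - 0.5 * config.behavior_link * coupling_c)
    hits = int(rng.binomial(n_targets, p_hit))
    false_alarms = int(rng.binomial(n_nontargets, p_fa))
    return behavior_scores(hits, false_alarms, n_targets, n_nontargets)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class Cohort:
    """A generated cohort: subjects, paradigm, planted truth, lazy runs."""

    config: CohortConfig
    subjects: list[SubjectRecord]
    subject_table: pd.DataFrame
    design: TaskDesign
    atlas: NetworkAtlas
    mask: Mask
    ground_truth: GroundTruth

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def simulate(self, subject_id: str, condition: str) -> BoldRun:
        s = self.subject(subject_id)
        design = self.design if condition == TASK else None
        return simulate_run(s, condition, self.atlas, design, self.config, self.mask)

    def iter_runs(self):
        """Yield all 2 x n_subjects runs (rest then task per subject)."""
        for s in self.subjects:
            yield self.simulate(s.id, REST)
            yield self.simulate(s.id, TASK)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort: demographics, latent couplings, behavior, design.

    Ages are uniform on the configured range, sex is Bernoulli(1/2).  The
    subject's resting hub coupling is ``hub_base + age_slope (age - mid)``
    plus subject noise; the task-state coupling adds ``task_coupling_delta``
    plus a subject-specific modulation whose spread (``delta_subject_sd``)
    is what links task-rest centrality differences to behavior.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    atlas = generate_network_maps(
        config.grid_dims,
        config.k_networks,
        seed=config.seed,
        n_artifacts=config.n_artifacts,
        sigma=config.blob_sigma,
    )
    mask = default_mask(config.grid_dims)
    design = make_nback_design(
        block_seconds=config.block_seconds,
        instruction_seconds=config.instruction_seconds,
        trial_seconds=config.trial_seconds,
        seed=config.seed,
    )
    if design.total_seconds > config.n_timepoints_task * config.tr_seconds + 1e-9:
        raise ConfigError(
            f"task design ({design.total_seconds:.0f}s) exceeds the task run "
            f"({config.n_timepoints_task * config.tr_seconds:.0f}s)"
        )

    subjects: list[SubjectRecord] = []
    rows = []
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:03d}"
        age = float(rng.uniform(*config.age_range_years))
        sex = int(rng.integers(0, 2))
        eps = float(rng.normal(0.0, config.coupling_subject_sd))
        eta = float(rng.normal(0.0, config.delta_subject_sd))
        rest_coupling = (
            config.hub_base_coupling + config.age_slope * (age - config.age_midpoint) + eps
        )
        hub_coupling = rest_coupling + config.task_coupling_delta + eta
        strengths = np.clip(
            1.0 + rng.normal(0.0, config.network_strength_sd, atlas.k_total), 0.3, None
        )
        subject = SubjectRecord(
            id=sid, age_years=age, sex=sex,
            hub_coupling=hub_coupling, rest_coupling=rest_coupling,
            network_strengths=strengths,
        )
        subjects.append(subject)
        scores = simulate_behavior(subject, config)
        rows.append(
            {
                "subject_id": sid,
                "age": age,
                "sex": sex,
                "hits": scores.hits,
                "false_alarms": scores.false_alarms,
            }
        )
    table = pd.DataFrame(rows)
    ground_truth = GroundTruth(
        atlas=atlas,
        mask=mask,
        config=config,
        subjects=subjects,
        design=design,
        activation_amplitudes=activation_amplitudes(atlas, config),
        coupling_deltas=coupling_deltas(atlas, config),
        age_slopes=network_age_slopes(atlas, config),
    )
    return Cohort(
        config=config,
        subjects=subjects,
        subject_table=table,
        design=design,
        atlas=atlas,
        mask=mask,
        ground_truth=ground_truth,
    )
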