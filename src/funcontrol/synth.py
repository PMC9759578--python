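"""Synthetic BOLD cohorts for a placebo-controlled stimulant crossover design.

Generates multi-run, multi-session ROI timeseries with the statistical
structure the downstream analysis assumes, so the whole pipeline is
testable without any imaging download:

* two groups — a clinical group scanned once on drug (MPH) and once on
  placebo in counterbalanced order, and a typically-developing (TD)
  group scanned twice unmedicated;
* three scan contexts per session (rest 2 x 150 volumes, go/no-go
  2 x 195, rewarded go/no-go 4 x 185; TR 2 s) at full scale;
* network-structured VAR(1) dynamics ``x(t+1) = A x(t) + eps`` with the
  group/drug effect expressed as a coupling increment on the
  within-network edges of designated effect networks;
* motion spike processes producing realistic framewise displacement,
  with matched rank-one spike artifacts injected into the signal (the
  motion-connectivity confound the cleaning stage must remove);
* slow drift plus global/white-matter/CSF nuisance components.

All randomness descends from a single integer seed through
``numpy.random.SeedSequence``, so identical configurations reproduce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS_13",
    "DESK_NETWORKS",
    "CohortConfig",
    "GroundTruth",
    "SessionInfo",
    "SubjectRecord",
    "Cohort",
    "SessionContextData",
    "RunData",
    "default_network_assignment",
    "make_atlas",
    "make_cohort",
    "simulate_var",
    "simulate_session",
    "make_nifti_fixture",
]

NETWORKS_13 = (
    "cingulo_opercular",
    "fronto_parietal",
    "dorsal_attention",
    "ventral_attention",
    "salience",
    "somatomotor_dorsal",
    "somatomotor_ventral",
    "visual",
    "auditory",
    "medial_temporal",
    "reward",
    "parietal_memory",
    "default_mode",
)
#: Desk-scale subset used by the default 40-ROI configuration.
DESK_NETWORKS = ("default_mode", "fronto_parietal", "somatomotor_dorsal", "visual")

FULL_SCALE_CONTEXTS = (("rest", 2, 150), ("gonogo", 2, 195), ("rewarded_gonogo", 4, 185))

GROUP_ADHD = "ADHD"
GROUP_TD = "TD"
CONDITION_MPH = "mph"
CONDITION_PLACEBO = "placebo"


def default_network_assignment(
    n_rois: int, networks: Sequence[str] = DESK_NETWORKS
) -> dict[int, str]:
    """Contiguous, near-equal blocks of ROIs per network label."""
    if n_rois < len(networks):
        raise ValueError("need at least one ROI per network")
    bounds = np.linspace(0, n_rois, len(networks) + 1).astype(int)
    assignment: dict[int, str] = {}
    for k, name in enumerate(networks):
        for i in range(bounds[k], bounds[k + 1]):
            assignment[i] = name
    return assignment


@dataclass(frozen=True)
class CohortConfig:
    """Generative configuration for one synthetic cohort.

    ``group_effect_size`` is the additive coupling increment applied to
    every within-network edge of the ``effect_networks`` in the clinical
    group's placebo sessions; on MPH the increment is scaled by
    ``1 - drug_recovery_fraction`` (1.0 = full normalization).
    ``motion_scale_by_cell`` maps (group, condition) to the mean
    small-spike magnitude in mm; the clinical-on-placebo cell moves
    most, the clinical-on-drug cell least, TD in between, mirroring the
    acute behavioral response the analysis conditions on.
    """

    n_per_group: int = 10
    contexts: tuple = FULL_SCALE_CONTEXTS
    tr_seconds: float = 2.0
    n_rois: int = 40
    networks: tuple = DESK_NETWORKS
    network_assignment: Mapping[int, str] | None = None
    effect_networks: frozenset = frozenset({"somatomotor_dorsal"})
    group_effect_size: float = 0.06
    drug_recovery_fraction: float = 1.0
    # two-component motion model: frequent small (sub-threshold) spikes
    # whose scale depends on the (group, condition) cell — restlessness,
    # the component the drug damps and the raw-FD responder rule reads —
    # and rare large censorable spikes with a cell-independent scale, so
    # the censored-frame budget stays comparable across cells
    motion_spike_rate: float = 0.01
    motion_large_shift: float = 0.25
    motion_large_scale: float = 0.2
    motion_small_rate: float = 0.15
    motion_small_cap: float = 0.18
    motion_scale_by_cell: Mapping[tuple, float] = field(
        default_factory=lambda: {
            (GROUP_ADHD, CONDITION_PLACEBO): 0.10,
            (GROUP_ADHD, CONDITION_MPH): 0.05,
            (GROUP_TD, CONDITION_PLACEBO): 0.07,
        }
    )
    motion_jitter_mm: float = 0.01
    # between-subject spread of motion propensity: each subject carries a
    # lognormal multiplier (sigma below) on the cell spike scale, constant
    # across their sessions, so in-scanner motion varies within every cell
    motion_subject_sigma: float = 0.5
    coupling_within: float = 0.25
    coupling_between: float = 0.04
    coupling_jitter: float = 0.01
    spectral_radius: float = 0.6
    innovation_sd: float = 1.0
    drift_scale: float = 0.5
    nuisance_scale: float = 0.5
    artifact_scale: float = 2.0
    seed: int = 0

    def resolved_assignment(self) -> dict[int, str]:
        if self.network_assignment is not None:
            return dict(self.network_assignment)
        return default_network_assignment(self.n_rois, self.networks)

    def validate(self) -> None:
        labels = set(self.resolved_assignment().values())
        for net in self.effect_networks:
            if net not in labels:
                raise ValueError(f"effect network {net!r} is not an assigned network label")
        if not (0.0 <= self.drug_recovery_fraction <= 1.0):
            raise ValueError("drug_recovery_fraction must lie in [0, 1]")
        if self.group_effect_size < 0:
            raise ValueError("group_effect_size must be >= 0")
        if not (0 < self.spectral_radius < 1):
            raise ValueError("spectral_radius must lie in (0, 1)")
        for name, n_runs, volumes in self.contexts:
            if n_runs < 1 or volumes < 10:
                raise ValueError(f"context {name!r} must have >= 1 run of >= 10 volumes")


@dataclass(frozen=True)
class GroundTruth:
    """Per-session generative parameters for one subject.

    ``A_true`` is the stable symmetric coupling matrix shared by every
    context of the session; only context noise seeds differ.
    """

    A_true: np.ndarray
    small_spike_rate: float
    small_spike_scale: float
    large_spike_rate: float
    large_spike_shift: float
    large_spike_scale: float
    artifact_loadings: np.ndarray
    nuisance_loadings: np.ndarray  # 3 x n_rois (global, wm, csf)
    drift_loadings: np.ndarray

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvalsh(self.A_true))))


@dataclass(frozen=True)
class SessionInfo:
    session_index: int
    condition: str
    ground_truth: GroundTruth
    seed: int


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: int
    sessions: tuple


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    subjects: tuple
    atlas: pd.DataFrame
    manifest: pd.DataFrame


@dataclass(frozen=True)
class RunData:
    data: np.ndarray  # ROI x T
    motion_params: np.ndarray  # 6 x T
    nuisance: pd.DataFrame  # T rows: global, wm, csf
    spike_frames: np.ndarray
    spike_magnitudes: np.ndarray


@dataclass(frozen=True)
class SessionContextData:
    context: str
    runs: tuple


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def make_atlas(
    n_rois: int,
    networks: Sequence[str] = DESK_NETWORKS,
    assignment: Mapping[int, str] | None = None,
    spacing_mm: float = 12.0,
) -> pd.DataFrame:
    """Deterministic lattice atlas: roi_id, x, y, z (mm), network_label."""
    if assignment is None:
        assignment = default_network_assignment(n_rois, networks)
    side = int(np.ceil(n_rois ** (1.0 / 3.0)))
    coords = []
    for idx in range(n_rois):
        i, rem = divmod(idx, side * side)
        j, k = divmod(rem, side)
        coords.append(
            (
                (i - side / 2) * spacing_mm,
                (j - side / 2) * spacing_mm,
                (k - side / 2) * spacing_mm,
            )
        )
    return pd.DataFrame(
        {
            "roi_id": [f"roi{idx:03d}" for idx in range(n_rois)],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "z": [c[2] for c in coords],
            "network_label": [assignment[idx] for idx in range(n_rois)],
        }
    )


# ---------------------------------------------------------------------------
# ground-truth coupling
# ---------------------------------------------------------------------------


def _base_coupling(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-structured symmetric coupling, rescaled to the target radius."""
    n = config.n_rois
    assignment = config.resolved_assignment()
    labels = np.array([assignment[i] for i in range(n)])
    same = labels[:, None] == labels[None, :]
    A = np.where(same, config.coupling_within, config.coupling_between).astype(float)
    noise = rng.normal(0.0, config.coupling_jitter, size=(n, n))
    A = A + (noise + noise.T) / 2.0
    np.fill_diagonal(A, 0.0)
    rho = np.max(np.abs(np.linalg.eigvalsh(A)))
    return A * (config.spectral_radius / rho)


def _effect_mask(config: CohortConfig) -> np.ndarray:
    assignment = config.resolved_assignment()
    labels = np.array([assignment[i] for i in range(config.n_rois)])
    in_effect = np.isin(labels, sorted(config.effect_networks))
    mask = np.outer(in_effect, in_effect)
    np.fill_diagonal(mask, False)
    return mask


def _with_effect(A: np.ndarray, config: CohortConfig, increment: float) -> np.ndarray:
    if increment == 0.0:
        return A
    out = A.copy()
    out[_effect_mask(config)] += increment
    rho = np.max(np.abs(np.linalg.eigvalsh(out)))
    if rho >= 0.98:
        raise ValueError(
            f"coupling increment {increment} destabilizes the system "
            f"(spectral radius {rho:.3f}); reduce group_effect_size"
        )
    return out


def _make_ground_truth(
    A: np.ndarray,
    config: CohortConfig,
    group: str,
    condition: str,
    rng: np.random.Generator,
    motion_multiplier: float = 1.0,
) -> GroundTruth:
    n = config.n_rois
    scale_map = dict(config.motion_scale_by_cell)
    key = (group, condition if group == GROUP_ADHD else CONDITION_PLACEBO)
    return GroundTruth(
        A_true=A,
        small_spike_rate=config.motion_small_rate,
        small_spike_scale=scale_map[key] * motion_multiplier,
        large_spike_rate=config.motion_spike_rate,
        large_spike_shift=config.motion_large_shift,
        large_spike_scale=config.motion_large_scale * motion_multiplier,
        artifact_loadings=np.abs(rng.normal(0.5, 0.2, size=n)),
        nuisance_loadings=np.vstack(
            [
                rng.normal(0.8, 0.2, size=n),
                rng.normal(0.3, 0.1, size=n),
                rng.normal(0.3, 0.1, size=n),
            ]
        ),
        drift_loadings=rng.normal(0.0, 1.0, size=n),
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def make_cohort(config: CohortConfig) -> Cohort:
    """Build the cohort manifest and per-subject/session ground truth.

    Clinical subjects receive one placebo session (within-effect-network
    coupling incremented by ``group_effect_size``) and one MPH session
    (increment scaled by ``1 - drug_recovery_fraction``), in an order
    counterbalanced by subject-index parity.  TD subjects receive two
    sessions with identical generative parameters.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *_ = root.spawn(1)
    rng = np.random.default_rng(cohort_ss)
    atlas = make_atlas(config.n_rois, config.networks, config.network_assignment)

    delta_placebo = config.group_effect_size
    delta_mph = config.group_effect_size * (1.0 - config.drug_recovery_fraction)

    subjects = []
    manifest_rows = []
    subject_specs = [(GROUP_ADHD, i) for i in range(config.n_per_group)] + [
        (GROUP_TD, i) for i in range(config.n_per_group)
    ]
    for group, idx in subject_specs:
        sid = f"sub-{group.lower()}{idx:03d}"
        age = float(rng.uniform(8.0, 12.0))
        sex = int(rng.integers(0, 2))
        motion_multiplier = float(np.exp(rng.normal(0.0, config.motion_subject_sigma)))
        A_base = _base_coupling(config, rng)
        if group == GROUP_ADHD:
            conditions = (
                (CONDITION_MPH, CONDITION_PLACEBO)
                if idx % 2 == 0
                else (CONDITION_PLACEBO, CONDITION_MPH)
            )
            deltas = {CONDITION_PLACEBO: delta_placebo, CONDITION_MPH: delta_mph}
        else:
            conditions = (CONDITION_PLACEBO, CONDITION_PLACEBO)
            deltas = {CONDITION_PLACEBO: 0.0}
        sessions = []
        for s_idx, condition in enumerate(conditions, start=1):
            A = _with_effect(A_base, config, deltas[condition])
            group_code = 0 if group == GROUP_ADHD else 1
            gt_rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 7, group_code, idx, s_idx))
            )
            gt = _make_ground_truth(A, config, group, condition, gt_rng, motion_multiplier)
            session_seed = int(
                np.random.SeedSequence((config.seed, 11, group_code, idx, s_idx))
                .generate_state(1)[0]
                % (2**31)
            )
            sessions.append(
                SessionInfo(
                    session_index=s_idx, condition=condition, ground_truth=gt, seed=session_seed
                )
            )
            for context_name, n_runs, _volumes in config.contexts:
                for run_idx in range(1, n_runs + 1):
                    manifest_rows.append(
                        {
                            "subject_id": sid,
                            "group": group,
                            "session_index": s_idx,
                            "condition": condition,
                            "context": context_name,
                            "run_index": run_idx,
                        }
                    )
        subjects.append(
            SubjectRecord(subject_id=sid, group=group, age=age, sex=sex, sessions=tuple(sessions))
        )
    manifest = pd.DataFrame(manifest_rows)
    return Cohort(config=config, subjects=tuple(subjects), atlas=atlas, manifest=manifest)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_var(
    A: np.ndarray,
    T: int,
    rng: np.random.Generator,
    innovation_sd: float = 1.0,
    burn_in: int = 50,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Realize ``x(t+1) = A x(t) + eps`` for T frames after burn-in.

    Refuses unstable coupling (spectral radius >= 1), since the process
    would be non-stationary.
    """
    A = np.asarray(A, dtype=float)
    rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if rho >= 1.0:
        raise ValueError(f"coupling matrix is unstable (spectral radius {rho:.4f} >= 1)")
    n = A.shape[0]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    out = np.empty((n, T))
    for _ in range(burn_in):
        eps = rng.normal(0.0, innovation_sd, size=n) if innovation_sd > 0 else 0.0
        x = A @ x + eps
    for t in range(T):
        eps = rng.normal(0.0, innovation_sd, size=n) if innovation_sd > 0 else 0.0
        x = A @ x + eps
        out[:, t] = x
    return out


def _ar1(T: int, rng: np.random.Generator, phi: float = 0.95) -> np.ndarray:
    innov_sd = np.sqrt(1.0 - phi**2)
    x = rng.normal(0.0, 1.0)
    out = np.empty(T)
    for t in range(T):
        x = phi * x + rng.normal(0.0, innov_sd)
        out[t] = x
    return out


def _simulate_motion(
    T: int,
    rng: np.random.Generator,
    jitter_mm: float,
    gt: GroundTruth,
    small_cap: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """6 x T motion parameters: white jitter plus single-frame spike offsets.

    Small spikes (capped at ``small_cap`` mm, i.e. below the censoring
    threshold) model cell-dependent restlessness; large spikes model the
    abrupt movements censoring removes.
    """
    params = np.vstack(
        [
            rng.normal(0.0, jitter_mm, size=(3, T)),
            rng.normal(0.0, jitter_mm / 50.0, size=(3, T)),
        ]
    )
    frames_all, mags_all = [], []
    for rate, draw in (
        (
            gt.small_spike_rate,
            lambda k: np.minimum(rng.exponential(gt.small_spike_scale, k), small_cap),
        ),
        (
            gt.large_spike_rate,
            lambda k: gt.large_spike_shift + rng.exponential(gt.large_spike_scale, k),
        ),
    ):
        if rate <= 0:
            continue
        frames = np.flatnonzero(rng.random(T - 1) < rate) + 1  # never frame 0
        mags = draw(frames.size)
        axes = rng.integers(0, 3, size=frames.size)
        for f, m, ax in zip(frames, mags, axes):
            params[ax, f] += m
        frames_all.append(frames)
        mags_all.append(mags)
    if frames_all:
        frames = np.concatenate(frames_all)
        mags = np.concatenate(mags_all)
        order = np.argsort(frames)
        return params, frames[order], mags[order]
    return params, np.array([], dtype=int), np.array([])


def simulate_session(
    ground_truth: GroundTruth,
    context: tuple[str, int, int],
    seed: int,
    config: CohortConfig,
) -> SessionContextData:
    """Simulate every run of one scan context for one session.

    Each run is a VAR(1) realization of the session's coupling matrix
    plus additive drift, global/tissue nuisance components with per-ROI
    loadings, and a rank-one motion-locked artifact whose spike times
    match the generated motion parameters (so FD computed downstream
    reflects the injected events).
    """
    import zlib

    name, n_runs, T = context
    root = np.random.SeedSequence((seed, zlib.crc32(name.encode())))
    run_seeds = root.spawn(n_runs)
    runs = []
    for run_ss in run_seeds:
        rng = np.random.default_rng(run_ss)
        X = simulate_var(ground_truth.A_true, T, rng, innovation_sd=config.innovation_sd)

        t = np.arange(T) / max(T - 1, 1)
        drift = rng.normal(0.0, 1.0) * t + rng.normal(0.0, 0.5) * np.cos(np.pi * t)
        X = X + config.drift_scale * np.outer(ground_truth.drift_loadings, drift)

        g, wm, csf = (_ar1(T, rng) for _ in range(3))
        for load, sig in zip(ground_truth.nuisance_loadings, (g, wm, csf)):
            X = X + config.nuisance_scale * np.outer(load, sig)

        params, frames, mags = _simulate_motion(
            T, rng, config.motion_jitter_mm, ground_truth, config.motion_small_cap
        )
        spike_series = np.zeros(T)
        spike_series[frames] = mags
        X = X + config.artifact_scale * np.outer(ground_truth.artifact_loadings, spike_series)

        runs.append(
            RunData(
                data=X,
                motion_params=params,
                nuisance=pd.DataFrame({"global": g, "wm": wm, "csf": csf}),
                spike_frames=frames,
                spike_magnitudes=mags,
            )
        )
    return SessionContextData(context=name, runs=tuple(runs))


# ---------------------------------------------------------------------------
# volumetric fixture
# ---------------------------------------------------------------------------


def make_nifti_fixture(
    timeseries: np.ndarray,
    atlas: pd.DataFrame,
    voxel_size_mm: float = 3.0,
    pad_voxels: int = 4,
):
    """Pack ROI timeseries into a small 4-D NIfTI image for extraction tests.

    Each ROI's series is written into the single voxel nearest its atlas
    coordinate; the affine is diagonal with ``voxel_size_mm`` spacing.
    ROIs whose coordinates fall outside the padded bounding box of the
    in-range ROIs are simply not written, emulating a truncated field of
    view.
    """
    import nibabel as nib

    coords = atlas[["x", "y", "z"]].to_numpy(dtype=float)
    lo = coords.min(axis=0) - pad_voxels * voxel_size_mm
    shape = np.ceil((coords.max(axis=0) - lo) / voxel_size_mm).astype(int) + 2 * pad_voxels
    T = timeseries.shape[1]
    vol = np.zeros((*shape, T))
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    for row_idx in range(len(atlas)):
        ijk = np.round((coords[row_idx] - lo) / voxel_size_mm).astype(int)
        if np.all(ijk >= 0) and np.all(ijk < shape):
            vol[tuple(ijk)] = timeseries[row_idx]
    return nib.Nifti1Image(vol, affine)
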