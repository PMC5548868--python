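"""Synthetic rs-fMRI cohorts with known ground truth.

Generates two diagnostic groups whose ROI correlation structure differs on a
small planted edge set, optional nuisance-correlated edges (age, sex,
medication …), head-motion traces with occasional spikes, tissue nuisance
signals partially leaked into the ROI series, and an "external" cohort
drawn with a different scanner profile (shifted TR, extra site noise).
Everything is deterministic given the spec and its seed.

The generator emulates the statistical structure the analysis assumes — it
does not model hemodynamics, volumes or scanner physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import MotionTrace, NuisanceSignals, RoiTimeSeries

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruth",
    "Participant",
    "repair_correlation",
    "make_group_covariances",
    "simulate_participant",
    "simulate_motion",
    "simulate_nuisance",
    "generate_cohort",
    "external_spec",
    "cohort_attribute_table",
]

#: Eigenvalue floor used by the positive-definiteness repair.
EIG_CLIP = 1e-6


@dataclass
class SyntheticCohortSpec:
    """Study-design parameters of a simulated two-group cohort.

    ``planted_edges`` receive a correlation shift of ``effect_delta`` in the
    patient group; ``nv_edges`` maps a nuisance-variable name to a list of
    ``((i, j), slope)`` entries adding attribute-proportional correlation
    shifts per participant.  Planted and nuisance edge sets must not
    overlap.  The defaults mirror a single-site 3-T resting-state protocol:
    200 frames at TR 2.0 s.
    """

    n_per_group: int
    n_rois: int = 30
    n_frames: int = 200
    tr_seconds: float = 2.0
    planted_edges: list[tuple[int, int]] = field(default_factory=list)
    effect_delta: float = 0.0
    nv_edges: dict[str, list[tuple[tuple[int, int], float]]] = field(
        default_factory=dict
    )
    base_density: float = 0.15
    ar_coef: float = 0.3
    motion_spike_prob: float = 0.02
    motion_spike_mm: float = 1.0
    motion_jitter_sd: float = 0.02
    nuisance_gain: float = 0.5
    site_noise_sd: float = 0.0
    p_medicated: float = 16 / 56  # patient-group medication rate
    seed: int = 0
    #: seed of the shared correlation structure; defaults to ``seed`` so an
    #: external cohort can resample participants under the same structure
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rois < 4:
            raise ValueError("n_rois must be ≥ 4")
        if abs(self.effect_delta) > 0.6:
            raise ValueError("|effect_delta| must be ≤ 0.6")
        if not 0.0 <= self.motion_spike_prob <= 1.0:
            raise ValueError("motion_spike_prob must lie in [0, 1]")
        planted = {tuple(sorted(e)) for e in self.planted_edges}
        nv = {
            tuple(sorted(edge))
            for entries in self.nv_edges.values()
            for edge, _ in entries
        }
        overlap = planted & nv
        if overlap:
            raise ValueError(f"planted and nuisance edges overlap: {sorted(overlap)}")
        for i, j in planted | nv:
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois and i != j):
                raise ValueError(f"edge ({i}, {j}) outside ROI range")

    @property
    def roi_names(self) -> list[str]:
        return [f"ROI{k:03d}" for k in range(self.n_rois)]


@dataclass
class GroundTruth:
    """What was planted; stored alongside a cohort, never fed to the pipeline."""

    planted_edges: list[tuple[int, int]]
    effect_delta: float
    target_difference: dict[tuple[int, int], float]
    group_assignment: dict[str, int]
    attributes: pd.DataFrame
    spike_frames: dict[str, list[int]]
    nv_edges: dict[str, list[tuple[tuple[int, int], float]]]

    def to_dict(self) -> dict:
        return {
            "planted_edges": [list(e) for e in self.planted_edges],
            "effect_delta": self.effect_delta,
            "target_difference": {
                f"{i},{j}": v for (i, j), v in self.target_difference.items()
            },
            "group_assignment": self.group_assignment,
            "attributes": self.attributes.reset_index().to_dict(orient="list"),
            "spike_frames": self.spike_frames,
            "nv_edges": {
                name: [[list(edge), slope] for edge, slope in entries]
                for name, entries in self.nv_edges.items()
            },
        }


@dataclass
class Participant:
    participant_id: str
    series: RoiTimeSeries
    motion: MotionTrace
    nuisance: NuisanceSignals
    attributes: dict


def repair_correlation(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to a unit-diagonal positive-definite one.

    Eigenvalues are clipped at ``EIG_CLIP``, the matrix reconstructed and
    rescaled to unit diagonal.  Returns the repaired matrix and the maximum
    absolute entry distortion; already-PD inputs come back bit-unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    sym = 0.5 * (matrix + matrix.T)
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() >= EIG_CLIP and np.allclose(np.diag(sym), 1.0, atol=1e-12):
        return matrix, 0.0
    clipped = (eigvec * np.maximum(eigval, EIG_CLIP)) @ eigvec.T
    d = np.sqrt(np.diag(clipped))
    repaired = clipped / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.max(np.abs(repaired - sym)))


def _baseline_correlation(spec: SyntheticCohortSpec) -> np.ndarray:
    """Shared raw baseline: unit diagonal, off-diagonals ~ N(0, base_density²)."""
    structure_seed = spec.structure_seed if spec.structure_seed is not None else spec.seed
    rng = np.random.default_rng([structure_seed, 101])
    n = spec.n_rois
    raw = np.eye(n)
    off = rng.normal(0.0, spec.base_density, size=(n, n))
    off = 0.5 * (off + off.T)
    raw += off - np.diag(np.diag(off))
    return np.clip(raw - np.diag(np.diag(raw)) , -0.97, 0.97) + np.eye(n)


def _apply_edge_shifts(
    base: np.ndarray, shifts: dict[tuple[int, int], float]
) -> np.ndarray:
    out = base.copy()
    bad = []
    for (i, j), delta in shifts.items():
        v = out[i, j] + delta
        if abs(v) >= 1.0:
            bad.append((i, j))
        out[i, j] = out[j, i] = v
    if bad:
        raise ValueError(
            "correlation shift pushed edges out of (-1, 1); offending edges: "
            + ", ".join(str(e) for e in sorted(tuple(sorted(e)) for e in bad))
        )
    return out


def make_group_covariances(
    spec: SyntheticCohortSpec, with_report: bool = False
):
    """Control- and patient-group ROI correlation matrices.

    The raw matrices share the baseline structure and differ by exactly
    ``effect_delta`` on the planted edges; each is then repaired to positive
    definiteness (eigenvalue clipping + unit-diagonal rescale).  With
    ``with_report=True`` a dict with the per-matrix max entry distortion and
    the post-repair planted-edge differences is returned as a third value.
    """
    base = _baseline_correlation(spec)
    shifts = {tuple(e): spec.effect_delta for e in spec.planted_edges}
    raw_b = _apply_edge_shifts(base, shifts)
    cov_a, dist_a = repair_correlation(base)
    cov_b, dist_b = repair_correlation(raw_b)
    if not with_report:
        return cov_a, cov_b
    report = {
        "max_distortion_control": dist_a,
        "max_distortion_patient": dist_b,
        "target_difference": {
            tuple(sorted(e)): float(cov_b[e[0], e[1]] - cov_a[e[0], e[1]])
            for e in spec.planted_edges
        },
    }
    return cov_a, cov_b, report


def simulate_participant(
    cov: np.ndarray,
    n_frames: int,
    tr_seconds: float,
    seed,
    ar_coef: float = 0.3,
    participant_id: str = "sub-000",
    roi_names: list[str] | None = None,
) -> RoiTimeSeries:
    """Zero-mean Gaussian ROI series with instantaneous correlation ``cov``.

    Frames follow a stationary AR(1) process x_t = φ x_{t−1} + √(1−φ²) L ε_t
    whose marginal covariance equals ``cov`` exactly; ``ar_coef=0`` gives
    temporally white frames.
    """
    cov = np.asarray(cov, dtype=float)
    if not 0.0 <= ar_coef < 1.0:
        raise ValueError("ar_coef must lie in [0, 1)")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    n_rois = cov.shape[0]
    innov = rng.standard_normal((n_frames, n_rois)) @ chol.T
    data = np.empty_like(innov)
    data[0] = innov[0]
    scale = np.sqrt(1.0 - ar_coef**2)
    for t in range(1, n_frames):
        data[t] = ar_coef * data[t - 1] + scale * innov[t]
    if roi_names is None:
        roi_names = [f"ROI{k:03d}" for k in range(n_rois)]
    return RoiTimeSeries(
        participant_id=participant_id,
        data=data,
        tr_seconds=tr_seconds,
        roi_names=roi_names,
    )


def simulate_motion(
    n_frames: int,
    spike_prob: float,
    spike_mm: float,
    seed,
    jitter_sd: float = 0.02,
) -> tuple[MotionTrace, list[int]]:
    """Six-parameter motion trace: Gaussian jitter plus isolated spikes.

    Spike frames (drawn per frame with probability ``spike_prob`` away from
    the series edges) add ``spike_mm`` to the x-translation for that single
    frame, so both adjacent frame-to-frame displacements exceed a 0.5 mm
    scrub threshold whenever ``spike_mm`` clearly dominates the jitter.
    Rotations are stored as mm-equivalent values at a 50 mm head radius.
    Returns the trace and the spike frame indices.
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, jitter_sd, size=(n_frames, 6)) if jitter_sd > 0 else np.zeros((n_frames, 6))
    spikes: list[int] = []
    if spike_prob > 0 and n_frames > 2:
        hit = rng.random(n_frames) < spike_prob
        hit[0] = hit[-1] = False
        spikes = [int(t) for t in np.flatnonzero(hit)]
        for t in spikes:
            data[t, 0] += spike_mm
    return MotionTrace(data=data, rotation_units="mm"), spikes


def simulate_nuisance(
    n_frames: int, tr_seconds: float, seed
) -> NuisanceSignals:
    """WM / CSF / whole-brain traces: low-frequency sinusoids plus noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * tr_seconds
    cols = []
    for _ in range(3):
        freq = rng.uniform(0.01, 0.04)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.5)
        cols.append(amp * np.sin(2 * np.pi * freq * t + phase)
                    + rng.normal(0.0, 0.3, size=n_frames))
    return NuisanceSignals(data=np.column_stack(cols))


def _nv_scale(name: str, value: float) -> float:
    """Attribute value on the scale multiplying an nv_edges slope."""
    if name == "age":
        return (value - 31.0) / 10.0
    return float(value)


def _draw_attributes(rng: np.random.Generator, diagnosis: int, spec) -> dict:
    age = float(np.clip(rng.normal(31.0, 9.0), 18.0, 65.0))
    sex = int(rng.random() < 0.5)
    handedness = int(rng.random() < 0.93)  # 1 = right-handed
    medicated = diagnosis == 1 and rng.random() < spec.p_medicated
    med_antidepressant = int(medicated and rng.random() < 16 / 16)
    med_antipsychotic = int(medicated and rng.random() < 4 / 16)
    med_anxiolytic = int(medicated and rng.random() < 2 / 16)
    ybocs = float(np.clip(rng.normal(21.1, 6.3), 0, 40)) if diagnosis == 1 else np.nan
    return {
        "diagnosis": diagnosis,
        "age": age,
        "sex": sex,
        "handedness": handedness,
        "med_anxiolytic": med_anxiolytic,
        "med_antidepressant": med_antidepressant,
        "med_antipsychotic": med_antipsychotic,
        "ybocs": ybocs,
    }


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[Participant], GroundTruth]:
    """Balanced two-group cohort with planted and nuisance-linked structure.

    Per participant: attributes are drawn, the group covariance receives the
    attribute-proportional nuisance-edge shifts and is re-repaired, ROI
    series are simulated, nuisance signals are leaked into the series with
    gain ``nuisance_gain``, optional site noise is added, and a motion trace
    with spikes is attached.  Identical spec + seed reproduces the cohort
    bit for bit.
    """
    if spec.n_per_group == 0:
        truth = GroundTruth(
            planted_edges=[tuple(e) for e in spec.planted_edges],
            effect_delta=spec.effect_delta,
            target_difference={},
            group_assignment={},
            attributes=pd.DataFrame(),
            spike_frames={},
            nv_edges=spec.nv_edges,
        )
        return [], truth
    cov_a, cov_b, report = make_group_covariances(spec, with_report=True)
    rng = np.random.default_rng([spec.seed, 202])
    participants: list[Participant] = []
    spike_frames: dict[str, list[int]] = {}
    group_assignment: dict[str, int] = {}
    attr_rows = []
    n_total = 2 * spec.n_per_group
    for idx in range(n_total):
        diagnosis = idx % 2  # alternating → balanced groups
        pid = f"sub-{idx:03d}"
        attrs = _draw_attributes(rng, diagnosis, spec)
        base = (cov_b if diagnosis == 1 else cov_a).copy()
        shifts = {}
        for name, entries in spec.nv_edges.items():
            scale = _nv_scale(name, attrs[name])
            for edge, slope in entries:
                key = tuple(edge)
                shifts[key] = shifts.get(key, 0.0) + slope * scale
        if shifts:
            base = _apply_edge_shifts(base, shifts)
        cov_i, _ = repair_correlation(base)
        series = simulate_participant(
            cov_i,
            spec.n_frames,
            spec.tr_seconds,
            seed=[spec.seed, 303, idx],
            ar_coef=spec.ar_coef,
            participant_id=pid,
            roi_names=spec.roi_names,
        )
        nuisance = simulate_nuisance(
            spec.n_frames, spec.tr_seconds, seed=[spec.seed, 404, idx]
        )
        leak_rng = np.random.default_rng([spec.seed, 505, idx])
        if spec.nuisance_gain > 0:
            loadings = leak_rng.normal(0.0, 1.0, size=(3, spec.n_rois))
            series.data += spec.nuisance_gain * nuisance.data @ loadings
        if spec.site_noise_sd > 0:
            series.data += leak_rng.normal(
                0.0, spec.site_noise_sd, size=series.data.shape
            )
        motion, spikes = simulate_motion(
            spec.n_frames,
            spec.motion_spike_prob,
            spec.motion_spike_mm,
            seed=[spec.seed, 606, idx],
            jitter_sd=spec.motion_jitter_sd,
        )
        participants.append(
            Participant(
                participant_id=pid,
                series=series,
                motion=motion,
                nuisance=nuisance,
                attributes=attrs,
            )
        )
        spike_frames[pid] = spikes
        group_assignment[pid] = diagnosis
        attr_rows.append({"participant_id": pid, **attrs})
    attributes = pd.DataFrame(attr_rows).set_index("participant_id")
    truth = GroundTruth(
        planted_edges=[tuple(e) for e in spec.planted_edges],
        effect_delta=spec.effect_delta,
        target_difference=report["target_difference"],
        group_assignment=group_assignment,
        attributes=attributes,
        spike_frames=spike_frames,
        nv_edges=spec.nv_edges,
    )
    return participants, truth


def external_spec(
    spec: SyntheticCohortSpec,
    n_per_group: int | None = None,
    seed: int | None = None,
    site_noise_sd: float = 0.5,
    tr_seconds: float = 2.411,
) -> SyntheticCohortSpec:
    """Spec for an external-validation cohort from a second scanner.

    Same planted edges and baseline structure (the spec's seed governs the
    shared covariances only through the planted design, which is copied),
    but a different sampling seed, a longer TR and extra site noise —
    mirroring acquisition on a different field-strength scanner.
    """
    structure = spec.structure_seed if spec.structure_seed is not None else spec.seed
    return replace(
        spec,
        n_per_group=n_per_group if n_per_group is not None else max(spec.n_per_group // 2, 2),
        seed=seed if seed is not None else spec.seed + 9001,
        structure_seed=structure,
        site_noise_sd=site_noise_sd,
        tr_seconds=tr_seconds,
    )


def cohort_attribute_table(participants: list[Participant]) -> pd.DataFrame:
    rows = [{"participant_id": p.participant_id, **p.attributes} for p in participants]
    return pd.DataFrame(rows).set_index("participant_id")
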