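"""Class-structured synthetic EEG for exercising the full pipeline.

Three generators cover the needs of the downstream stages:

* :func:`generate_class_segment` — a single labelled 10-s, 4-channel
  segment with a spectrally distinctive signature per class (posterior
  alpha for wake, slow high-amplitude delta for N3, lateralized rhythmic
  delta for LRDA, an evolving rhythm for seizures, ...).  The recipes
  are designed to be spectrally separable so metric learning has
  structure to find; they make no claim of clinical realism.
* :func:`generate_bs_signal` — burst suppression with a controllable
  suppressed-time fraction, built from alternating epochs of low-
  amplitude noise (< 10 µV) and high-amplitude oscillatory bursts.
* :func:`generate_cohort` — outcome-labelled long-term "patients" whose
  10-s state sequences follow a first-order Markov chain with a chosen
  stationary occupancy and a stickiness parameter that controls
  transition entropy.  Occupancy and dynamics are therefore
  independently plantable, mirroring the two prognostic axes the map
  analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neuromap.io import Recording
from neuromap.preprocess import DEFAULT_MONTAGE, Segment, TARGET_RATE

__all__ = [
    "CLASSES",
    "HEALTHY_CLASSES",
    "IIIC_CLASSES",
    "ClassRecipe",
    "CohortSpec",
    "CohortPatient",
    "generate_class_segment",
    "generate_bs_signal",
    "generate_cohort",
    "generate_training_set",
]

#: Canonical class order used throughout the package.
CLASSES = ["W", "N1", "N2", "N3", "REM", "SZ", "GPD", "LPD", "GRDA", "LRDA", "BS"]
HEALTHY_CLASSES = ["W", "N1", "N2", "N3", "REM"]
IIIC_CLASSES = ["SZ", "GPD", "LPD", "GRDA", "LRDA"]

_LEFT = (0, 1)  # F3-C3, C3-O1
_RIGHT = (2, 3)  # F4-C4, C4-O2


@dataclass(frozen=True)
class ClassRecipe:
    """Spectral recipe for one synthetic class.

    ``bands`` lists (center Hz, bandwidth Hz, amplitude µV) oscillations;
    ``modulation`` selects the temporal envelope; ``laterality`` restricts
    oscillatory content to one hemisphere's channel pair.
    """

    class_name: str
    bands: tuple[tuple[float, float, float], ...]
    modulation: str = "none"  # none | rhythmic | periodic | burst_suppression | evolving
    laterality: str = "generalized"  # generalized | left | right
    noise_amplitude: float = 8.0

    def __post_init__(self) -> None:
        for center, _bw, amp in self.bands:
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")
            if not 0.5 <= center <= 40.0:
                raise ValueError("center frequencies must lie in 0.5-40 Hz")


RECIPES: dict[str, ClassRecipe] = {
    "W": ClassRecipe("W", bands=((10.0, 1.0, 30.0),), noise_amplitude=5.0),
    "N1": ClassRecipe("N1", bands=((4.5, 0.8, 20.0), (6.5, 0.8, 20.0)), noise_amplitude=8.0),
    "N2": ClassRecipe("N2", bands=((5.0, 1.0, 25.0), (13.0, 0.5, 30.0)), modulation="rhythmic"),
    "N3": ClassRecipe("N3", bands=((1.0, 0.5, 75.0),), noise_amplitude=10.0),
    "REM": ClassRecipe("REM", bands=((5.0, 1.0, 10.0), (7.5, 1.0, 10.0)), noise_amplitude=6.0),
    "SZ": ClassRecipe("SZ", bands=((5.5, 2.5, 45.0),), modulation="evolving", noise_amplitude=8.0),
    "GPD": ClassRecipe("GPD", bands=((1.0, 0.0, 80.0),), modulation="periodic"),
    "LPD": ClassRecipe("LPD", bands=((1.0, 0.0, 80.0),), modulation="periodic", laterality="left"),
    "GRDA": ClassRecipe("GRDA", bands=((2.5, 0.5, 60.0),)),
    "LRDA": ClassRecipe("LRDA", bands=((2.5, 0.5, 60.0),), laterality="left"),
    "BS": ClassRecipe("BS", bands=((4.0, 1.0, 50.0),), modulation="burst_suppression"),
}


def _oscillation(rng: np.random.Generator, t: np.ndarray, center: float, bw: float, amp: float) -> np.ndarray:
    """One sinusoid with per-call random frequency (within the band) and phase."""
    f = center if bw == 0 else rng.uniform(center - bw / 2, center + bw / 2)
    phase = rng.uniform(0, 2 * np.pi)
    return amp * np.sin(2 * np.pi * f * t + phase)


def _sharp_wave(t: np.ndarray, period: float, width: float, amp: float, phase: float) -> np.ndarray:
    """Train of biphasic sharp transients with the given repetition period."""
    tt = np.mod(t + phase, period)
    pulse = np.exp(-0.5 * ((tt - width) / (width / 2.5)) ** 2)
    pulse -= 0.5 * np.exp(-0.5 * ((tt - 2.2 * width) / width) ** 2)
    return amp * pulse


def generate_class_segment(
    class_name: str,
    seed: int,
    patient_id: str = "synthetic",
    start_time: float = 0.0,
) -> Segment:
    """Generate one labelled 10-s, 4-channel segment of the given class.

    Deterministic for a given ``(class_name, seed)`` pair.
    """
    if class_name not in RECIPES:
        raise ValueError(f"unknown class {class_name!r}; expected one of {CLASSES}")
    recipe = RECIPES[class_name]
    rng = np.random.default_rng(np.random.SeedSequence((CLASSES.index(class_name), seed)))
    n = int(round(10.0 * TARGET_RATE))
    t = np.arange(n) / TARGET_RATE
    data = rng.normal(0.0, recipe.noise_amplitude, size=(4, n))

    if recipe.modulation == "burst_suppression":
        frac = rng.uniform(0.3, 0.7)
        seg = generate_bs_signal(frac, seed=int(rng.integers(2**31)), duration=10.0)
        seg.patient_id, seg.start_time = patient_id, start_time
        return seg

    channels = range(4) if recipe.laterality == "generalized" else (
        _LEFT if recipe.laterality == "left" else _RIGHT
    )
    for ch in channels:
        osc = np.zeros(n)
        if recipe.modulation == "periodic":
            period = 1.0 / recipe.bands[0][0]
            osc = _sharp_wave(t, period, width=0.07, amp=recipe.bands[0][2],
                              phase=rng.uniform(0, period))
        elif recipe.modulation == "evolving":
            # frequency ramps 3 -> 8 Hz while amplitude grows
            center, _bw, amp = recipe.bands[0]
            f0, f1 = 3.0, 8.0
            phase = rng.uniform(0, 2 * np.pi)
            inst_phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / 20.0) + phase
            ramp = np.linspace(0.4, 1.5, n)
            osc = amp * ramp * np.sin(inst_phase)
        elif recipe.modulation == "rhythmic":
            # background band(s) plus 1-s spindle-like bursts every ~3 s
            for center, bw, amp in recipe.bands[:-1]:
                osc += _oscillation(rng, t, center, bw, amp)
            center, bw, amp = recipe.bands[-1]
            burst = _oscillation(rng, t, center, bw, amp)
            gate = (np.mod(t + rng.uniform(0, 3), 3.0) < 1.0).astype(float)
            osc += burst * gate
        else:
            for center, bw, amp in recipe.bands:
                osc += _oscillation(rng, t, center, bw, amp)
        data[ch] += osc

    # wake alpha is posterior-dominant: attenuate the fronto-central pairs
    if class_name == "W":
        for ch in (0, 2):  # F3-C3, F4-C4 carry weaker alpha
            data[ch] *= 0.6

    return Segment(patient_id=patient_id, start_time=start_time, data=data, label=class_name)


def generate_bs_signal(
    suppression_fraction: float,
    seed: int,
    duration: float = 10.0,
) -> Segment:
    """Burst-suppression signal with a planted suppressed-time fraction.

    The signal alternates burst epochs (≈50 µV mixed oscillations) and
    suppression epochs (σ = 1.5 µV noise, envelope well below 10 µV).
    Epoch durations are jittered but kept ≥ 0.6 s wherever the target
    fraction permits, so the interval detector's minimum-duration rules
    do not clip them.  The realized suppressed-time fraction is within
    0.02 of the target by construction.
    """
    if not 0.0 <= suppression_fraction <= 1.0:
        raise ValueError("suppression_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fs = TARGET_RATE
    n = int(round(duration * fs))
    total_sup = suppression_fraction * duration
    total_burst = duration - total_sup

    # epoch plan: list of (is_suppression, n_samples)
    if total_sup < 0.3:
        plan = [(False, n)] if total_sup < 0.05 else [(False, n - int(total_sup * fs)), (True, int(total_sup * fs))]
    elif total_burst < 0.3:
        plan = [(True, n)] if total_burst < 0.05 else [(False, int(total_burst * fs)), (True, n - int(total_burst * fs))]
    else:
        n_cycles = max(1, min(3, int(min(total_sup, total_burst) // 1.2)))

        def _split(total: float) -> list[int]:
            w = rng.uniform(0.8, 1.2, n_cycles)
            durs = total * w / w.sum()
            return [int(round(d * fs)) for d in durs]

        sup_parts, burst_parts = _split(total_sup), _split(total_burst)
        plan = []
        for b, s in zip(burst_parts, sup_parts):
            plan.append((False, b))
            plan.append((True, s))
        # absorb rounding drift into the final epoch
        drift = n - sum(ns for _, ns in plan)
        plan[-1] = (plan[-1][0], plan[-1][1] + drift)

    data = np.empty((4, n))
    t_full = np.arange(n) / fs
    pos = 0
    for is_sup, n_ep in plan:
        if n_ep <= 0:
            continue
        sl = slice(pos, pos + n_ep)
        if is_sup:
            data[:, sl] = rng.normal(0.0, 1.5, size=(4, n_ep))
        else:
            tt = t_full[sl]
            for ch in range(4):
                ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
                data[ch, sl] = (
                    50.0 * np.sin(2 * np.pi * 4.3 * tt + ph1)
                    + 25.0 * np.sin(2 * np.pi * 9.1 * tt + ph2)
                    + rng.normal(0.0, 3.0, n_ep)
                )
        pos += n_ep
    return Segment(patient_id="synthetic", start_time=0.0, data=data, label="BS")


@dataclass
class CohortSpec:
    """Specification of a two-group, outcome-labelled synthetic cohort.

    ``occupancy`` maps each outcome group to its stationary distribution
    over the 11 classes (must sum to 1).  ``stickiness`` (in [0, 1))
    biases the Markov transition matrix toward self-transitions:
    P = (1 - s) · 1πᵀ + s · I, so higher stickiness means lower
    transition entropy while leaving the stationary occupancy unchanged.
    """

    n_patients: dict[str, int]  # outcome -> count, outcomes from {"good", "poor"}
    hours_per_patient: float
    occupancy: dict[str, np.ndarray]  # outcome -> (11,) distribution over CLASSES
    stickiness: dict[str, float] = field(default_factory=lambda: {"good": 0.5, "poor": 0.5})
    n_centers: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, dist in self.occupancy.items():
            dist = np.asarray(dist, dtype=float)
            if dist.shape != (len(CLASSES),):
                raise ValueError(f"occupancy for {grp!r} must have {len(CLASSES)} entries")
            if not np.isclose(dist.sum(), 1.0, atol=1e-8):
                raise ValueError(f"occupancy for {grp!r} must sum to 1")
            self.occupancy[grp] = dist
        for grp, n in self.n_patients.items():
            if n < 1:
                raise ValueError("n_patients must be >= 1")
            if grp not in self.occupancy:
                raise ValueError(f"no occupancy given for group {grp!r}")
        for s in self.stickiness.values():
            if not 0.0 <= s < 1.0:
                raise ValueError("stickiness must be in [0, 1)")


@dataclass
class CohortPatient:
    """One synthetic patient: state labels per 10-s epoch plus metadata."""

    patient_id: str
    center_id: str
    outcome: str
    labels: list[str]
    recording: Recording | None = None


def _markov_sequence(rng: np.random.Generator, pi: np.ndarray, s: float, length: int) -> np.ndarray:
    """Sample a state index sequence from P = (1-s)·1πᵀ + s·I."""
    k = pi.size
    seq = np.empty(length, dtype=int)
    seq[0] = rng.choice(k, p=pi)
    # at each step: with prob s stay, else draw fresh from pi
    stay = rng.random(length) < s
    fresh = rng.choice(k, size=length, p=pi)
    for t in range(1, length):
        seq[t] = seq[t - 1] if stay[t] else fresh[t]
    return seq


def generate_cohort(spec: CohortSpec, signals: bool = False) -> list[CohortPatient]:
    """Generate an outcome-labelled cohort of long-term synthetic patients.

    Each patient's 10-s state sequence is drawn from the group's Markov
    chain.  With ``signals=True`` the matching EEG is synthesized by
    concatenating class segments into a 4-channel bipolar Recording at
    200 Hz (slower; intended for end-to-end smoke runs).  Center IDs are
    assigned round-robin over ``spec.n_centers`` centers.
    """
    root = np.random.SeedSequence(spec.seed)
    n_epochs = int(round(spec.hours_per_patient * 3600.0 / 10.0))
    if n_epochs < 1:
        raise ValueError("hours_per_patient too small for one 10-s epoch")
    patients: list[CohortPatient] = []
    idx = 0
    for outcome in sorted(spec.n_patients):
        pi = spec.occupancy[outcome]
        s = spec.stickiness.get(outcome, 0.0)
        for j in range(spec.n_patients[outcome]):
            child = np.random.default_rng(root.spawn(1)[0])
            seq = _markov_sequence(child, pi, s, n_epochs)
            labels = [CLASSES[i] for i in seq]
            pid = f"{outcome}_{j:04d}"
            center = f"center_{idx % spec.n_centers}"
            recording = None
            if signals:
                seg_seed = int(child.integers(2**31))
                blocks = [
                    generate_class_segment(lab, seed=seg_seed + k, patient_id=pid).data
                    for k, lab in enumerate(labels)
                ]
                recording = Recording(
                    patient_id=pid,
                    channel_labels=DEFAULT_MONTAGE.channel_names,
                    sample_rate=TARGET_RATE,
                    data=np.concatenate(blocks, axis=1),
                    center_id=center,
                )
            patients.append(CohortPatient(pid, center, outcome, labels, recording))
            idx += 1
    return patients


def generate_training_set(
    n_per_class: int = 200,
    patients_per_class: int = 10,
    seed: int = 0,
    classes: list[str] | None = None,
) -> list[Segment]:
    """Balanced labelled segments for metric-learning fixtures.

    Segments of each class are spread over ``patients_per_class``
    distinct synthetic patients so patient-level cross-validation has
    groups to split on.
    """
    classes = list(classes or CLASSES)
    rng = np.random.default_rng(seed)
    segs: list[Segment] = []
    for cls in classes:
        base = int(rng.integers(2**30))
        for i in range(n_per_class):
            seg = generate_class_segment(
                cls,
                seed=base + i,
                patient_id=f"{cls}_p{i % patients_per_class:03d}",
                start_time=10.0 * (i // patients_per_class),
            )
            segs.append(seg)
    return segs
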