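"""Synthetic cohorts with planted dynamic communities and learning curves.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage is testable without any imaging data:

- **Time series**: each subject has region×time "rest" panels (default
  142 regions × 180 volumes at tr = 2 s).  Regions in the same planted
  module share a module-level Gaussian latent signal; independent region
  noise is scaled so the within-module correlation equals the subject's
  planted coupling strength.  Module memberships are piecewise-constant
  on half-window blocks (the step of the default window spec) and change
  between blocks through *cohesive* events (a group of regions moves
  from one module to the same target) and *disjoint* events (a lone
  region moves with no partner making the same move), at Poisson rates
  set per learner profile.
- **Behavior**: per-trial endpoint errors decay exponentially,
  error(t) = a·exp(−t/τ_day) + b + noise, with profile-specific time
  constants: FF fast both days, SS slow both days, SF slow day 1 / fast
  day 2.  τ is linked to the subject's planted coupling through
  ``effect_slope`` so faster learners have stronger coupling, giving
  the pipeline a recoverable monotone brain-behavior association.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .connectivity import TimeSeriesPanel, WindowSpec, window_slices
from . import io as dio

__all__ = ["CohortConfig", "GroundTruth", "generate_modular_timeseries",
           "generate_behavioral_trials", "generate_cohort", "Cohort"]

PROFILES = ("FF", "SS", "SF")
TARGET_ANGLES = (0, 45, 90, 135, 180, 225, 270, 315)
N_BINS = 40
TRIALS_PER_BIN = 8


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort."""

    n_subjects: int = 32
    n_regions: int = 142
    n_volumes: int = 180
    tr: float = 2.0
    n_modules_planted: int = 4
    subgroup_sizes: dict = field(
        default_factory=lambda: {"FF": 15, "SS": 10, "SF": 7}
    )
    coupling_strength_by_profile: dict = field(
        default_factory=lambda: {"FF": 0.8, "SS": 0.3, "SF": 0.55}
    )
    cohesion_rate_by_profile: dict = field(
        default_factory=lambda: {"FF": 0.8, "SS": 0.1, "SF": 0.4}
    )
    disjoint_rate_by_profile: dict = field(
        default_factory=lambda: {"FF": 0.1, "SS": 0.8, "SF": 0.4}
    )
    noise_sd: float = 1.0          # timeseries noise multiplier (1 = calibrated)
    trial_noise_sd: float = 2.0    # degrees, additive on trial error
    error_amplitude: float = 40.0  # degrees, initial error above baseline
    error_baseline: float = 5.0    # degrees, asymptotic error
    amplitude_sd: float = 2.0      # degrees, per-day spread of amplitude
    baseline_sd: float = 1.0       # degrees, per-day spread of baseline
    tau_by_profile: dict = field(
        default_factory=lambda: {
            "FF": (15.0, 10.0), "SS": (120.0, 110.0), "SF": (120.0, 15.0)
        }
    )
    coupling_jitter: float = 0.05  # per-subject uniform jitter on coupling
    tau_jitter_sd: float = 0.08    # log-scale per-day independent tau variability
    effect_slope: float = 1.5      # link coefficient: coupling → log learning rate
    window: WindowSpec = WindowSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subgroup_sizes.values()) != self.n_subjects:
            raise ValueError("subgroup sizes must sum to n_subjects")
        if set(self.subgroup_sizes) - set(PROFILES):
            raise ValueError(f"unknown profiles {set(self.subgroup_sizes) - set(PROFILES)}")
        for name, rates in (
            ("cohesion_rate", self.cohesion_rate_by_profile),
            ("disjoint_rate", self.disjoint_rate_by_profile),
        ):
            if any(r < 0 for r in rates.values()):
                raise ValueError(f"{name} must be >= 0")
        if any(not (0 < c < 1) for c in self.coupling_strength_by_profile.values()):
            raise ValueError("coupling strength must lie in (0, 1)")
        for taus in self.tau_by_profile.values():
            if any(t <= 0 for t in taus):
                raise ValueError("decay time constant tau must be positive")
        if self.n_modules_planted < 2 or self.n_modules_planted > self.n_regions // 2:
            raise ValueError("n_modules_planted must be in [2, n_regions/2]")
        if self.n_volumes < self.window.length:
            raise ValueError("series too short: n_volumes below one window span")

    def profile_of(self, subject: int) -> str:
        """Deterministic profile assignment: FF block, then SS, then SF."""
        if not 0 <= subject < self.n_subjects:
            raise ValueError(f"subject index {subject} out of range")
        bound = 0
        for prof in PROFILES:
            bound += self.subgroup_sizes.get(prof, 0)
            if subject < bound:
                return prof
        raise AssertionError("unreachable")

    def subject_coupling(self, subject: int) -> float:
        """Planted within-module correlation, jittered per subject."""
        prof = self.profile_of(subject)
        rng = derive_rng(self.seed, "coupling", subject)
        jit = rng.uniform(-self.coupling_jitter, self.coupling_jitter)
        return float(np.clip(self.coupling_strength_by_profile[prof] + jit, 0.05, 0.95))

    def subject_taus(self, subject: int) -> tuple[float, float]:
        """Per-day decay constants: coupling-linked scale plus independent
        day-to-day log-normal variability."""
        prof = self.profile_of(subject)
        rho = self.subject_coupling(subject)
        rho0 = self.coupling_strength_by_profile[prof]
        scale = float(np.exp(-self.effect_slope * (rho - rho0)))
        rng = derive_rng(self.seed, "tau-jitter", subject)
        day_jit = np.exp(self.tau_jitter_sd * rng.standard_normal(2))
        t1, t2 = self.tau_by_profile[prof]
        return t1 * scale * float(day_jit[0]), t2 * scale * float(day_jit[1])


@dataclass
class GroundTruth:
    """Planted structure for one subject's scan and behavior."""

    subject: int
    profile: str
    coupling: float
    partitions: np.ndarray       # L×N planted module labels per window
    tau_day1: float
    tau_day2: float
    cohesive_events: int
    disjoint_events: int

    def to_json(self) -> dict:
        d = asdict(self)
        d["partitions"] = self.partitions.tolist()
        return d


def _initial_membership(n_regions: int, n_modules: int) -> np.ndarray:
    return np.sort(np.arange(n_regions) % n_modules)


def _plant_switches(
    membership: np.ndarray,
    n_boundaries: int,
    coh_rate: float,
    dis_rate: float,
    n_modules: int,
    rng: np.random.Generator,
):
    """Per-block membership matrix with planted cohesive/disjoint events.

    Events never empty a module; a disjoint mover's (source, target) pair
    is kept distinct from every other move at the same boundary.
    """
    blocks = [membership.copy()]
    n_coh_total = n_dis_total = 0
    for _ in range(n_boundaries):
        cur = blocks[-1].copy()
        used_moves: set[tuple[int, int]] = set()
        moved: set[int] = set()
        for _ev in range(rng.poisson(coh_rate)):
            g = int(rng.integers(2, 4))  # group of 2-3 mutual movers
            src_sizes = np.bincount(cur, minlength=n_modules)
            candidates = np.flatnonzero(src_sizes >= g + 1)
            if candidates.size == 0:
                continue
            src = int(rng.choice(candidates))
            dst = int(rng.choice([m for m in range(n_modules) if m != src]))
            pool = [i for i in np.flatnonzero(cur == src) if i not in moved]
            if len(pool) < g or (src_sizes[src] - g) < 1:
                continue
            movers = rng.choice(pool, size=g, replace=False)
            cur[movers] = dst
            moved.update(int(i) for i in movers)
            used_moves.add((src, dst))
            n_coh_total += 1
        for _ev in range(rng.poisson(dis_rate)):
            src_sizes = np.bincount(cur, minlength=n_modules)
            candidates = np.flatnonzero(src_sizes >= 2)
            ok = False
            for _try in range(10):
                if candidates.size == 0:
                    break
                src = int(rng.choice(candidates))
                dst = int(rng.choice([m for m in range(n_modules) if m != src]))
                if (src, dst) in used_moves:
                    continue
                pool = [i for i in np.flatnonzero(cur == src) if i not in moved]
                if not pool:
                    continue
                mover = int(rng.choice(pool))
                ok = True
                break
            if not ok:
                continue
            cur[mover] = dst
            moved.add(mover)
            used_moves.add((src, dst))
            n_dis_total += 1
        blocks.append(cur)
    return np.stack(blocks), n_coh_total, n_dis_total


def generate_modular_timeseries(
    config: CohortConfig, subject: int, scan: int = 1
) -> tuple[TimeSeriesPanel, GroundTruth]:
    """One subject's region×time panel with planted dynamic communities."""
    prof = config.profile_of(subject)
    rho = config.subject_coupling(subject)
    rng = derive_rng(config.seed, "timeseries", subject, scan)
    N, T, K = config.n_regions, config.n_volumes, config.n_modules_planted
    step = config.window.step
    L = len(window_slices(T, config.window))
    n_blocks = (T + step - 1) // step
    blocks, n_coh, n_dis = _plant_switches(
        _initial_membership(N, K),
        n_blocks - 1,
        config.cohesion_rate_by_profile[prof],
        config.disjoint_rate_by_profile[prof],
        K,
        rng,
    )
    # volume t lives in block t // step
    block_of_t = np.minimum(np.arange(T) // step, n_blocks - 1)
    latents = rng.standard_normal((K, T))
    member_t = blocks[block_of_t]              # T×N
    signal = latents[member_t.T, np.arange(T)[None, :]]  # N×T
    sigma = config.noise_sd * np.sqrt((1.0 - rho) / rho)
    data = signal + sigma * rng.standard_normal((N, T))
    panel = TimeSeriesPanel(data=data, tr=config.tr, subject=f"sub-{subject:03d}")
    tau1, tau2 = config.subject_taus(subject)
    truth = GroundTruth(
        subject=subject,
        profile=prof,
        coupling=rho,
        partitions=blocks[:L],  # planted partition of window l = membership of block l
        tau_day1=tau1,
        tau_day2=tau2,
        cohesive_events=n_coh,
        disjoint_events=n_dis,
    )
    return panel, truth


def generate_behavioral_trials(config: CohortConfig, subject: int) -> pd.DataFrame:
    """Two days of learning trials with profile-specific error decay."""
    tau1, tau2 = config.subject_taus(subject)
    rng = derive_rng(config.seed, "behavior", subject)
    rows = []
    for day, tau in ((1, tau1), (2, tau2)):
        amp = config.error_amplitude + config.amplitude_sd * rng.standard_normal()
        base = config.error_baseline + config.baseline_sd * rng.standard_normal()
        for b in range(1, N_BINS + 1):
            targets = rng.permutation(TARGET_ANGLES)
            for j in range(TRIALS_PER_BIN):
                t = (b - 1) * TRIALS_PER_BIN + j + 1
                err = (
                    amp * np.exp(-t / tau)
                    + base
                    + config.trial_noise_sd * rng.standard_normal()
                )
                rows.append(
                    {"day": day, "trial": t, "bin": b,
                     "target_deg": int(targets[j]),
                     "error_deg": float(np.clip(err, -180.0, 180.0))}
                )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """In-memory synthetic cohort: paired rest panels, trials, ground truth."""

    config: CohortConfig
    panels: dict          # (subject, scan) -> TimeSeriesPanel
    trials: dict          # subject -> DataFrame
    truths: dict          # (subject, scan) -> GroundTruth

    @property
    def subjects(self) -> list[int]:
        return list(range(self.config.n_subjects))


def generate_cohort(
    config: CohortConfig, out_dir=None, overwrite: bool = False
) -> Cohort:
    """Full cohort: two rest scans + one trial table per subject.

    With ``out_dir``, writes one directory per subject (two timeseries
    files, trial table, ground-truth manifest), a region sidecar table,
    and a cohort manifest.
    """
    panels, trials, truths = {}, {}, {}
    for s in range(config.n_subjects):
        for scan in (1, 2):
            panel, truth = generate_modular_timeseries(config, s, scan)
            panels[(s, scan)] = panel
            truths[(s, scan)] = truth
        trials[s] = generate_behavioral_trials(config, s)
    cohort = Cohort(config=config, panels=panels, trials=trials, truths=truths)
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()):
            if not overwrite:
                raise FileExistsError(
                    f"output directory {out} exists; pass overwrite=True to replace"
                )
            shutil.rmtree(out)
        out.mkdir(parents=True, exist_ok=True)
        base_labels = _initial_membership(config.n_regions, config.n_modules_planted)
        dio.write_regions(
            out / "regions.tsv",
            [f"r{i:03d}" for i in range(config.n_regions)],
            [f"region_{i:03d}" for i in range(config.n_regions)],
            [int(m) + 1 if m < 5 else "none" for m in base_labels],
        )
        subject_dirs = []
        for s in range(config.n_subjects):
            sdir = out / f"sub-{s:03d}"
            sdir.mkdir()
            for scan in (1, 2):
                dio.write_panel(sdir / f"rest{scan}.tsv", panels[(s, scan)])
                dio.write_json(sdir / f"truth_rest{scan}.json", truths[(s, scan)].to_json())
            dio.write_trials(sdir / "trials.tsv", trials[s])
            subject_dirs.append(sdir.name)
        dio.write_json(out / "manifest.json", {
            "n_subjects": config.n_subjects,
            "subjects": subject_dirs,
            "profiles": {f"sub-{s:03d}": config.profile_of(s) for s in range(config.n_subjects)},
            "seed": config.seed,
            "tr": config.tr,
            "n_regions": config.n_regions,
            "n_volumes": config.n_volumes,
        })
    return cohort
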