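"""Synthetic event-related flanker-like designs with known ground truth.

The generator emulates a rapid event-related selective-attention experiment:
four 7-minute runs of 164 volumes at TR = 2.5 s, each starting with a 10 s
fixation baseline followed by 32 trials per condition (Congruent "C",
Incongruent "IC", Neutral "N") in random order, with inter-stimulus intervals
randomized on multiples of the TR.  Under the default geometry the mean
onset-to-onset interval — total acquisition time divided by trial count — is
4.27 s.

Ground truth for a synthetic subject is an impulse information delivery per
trial (alpha_C or alpha_IC bits; incongruent arrays carry a higher
information load), plus delayed inhibitory and secondary excitatory
deliveries scaled to the trial's amount.  Activity follows the IPC ODE, BOLD
follows HRF convolution, sampling at TR and additive noise.  Runs are
simulated independently (no activity carries across run boundaries).

An "isolated" mode enforces a minimum ISI so trial responses do not overlap;
the default rapid design overlaps trials, which biases trial-averaged
responses exactly as it does in real rapid event-related data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import EventTrain, IPCParams, simulate_ipc
from .forward import FINE_DT, NoiseModel, convolve_bold, sample_and_noise
from .hrf import HRFParams, hrf_kernel, DEFAULT_SUPPORT_S
from .timeseries import SampledBOLD, TimeSeries, time_grid
from .twostate import TwoStateParams

__all__ = [
    "Paradigm",
    "GroundTruth",
    "CapacityError",
    "generate_paradigm",
    "generate_subject",
    "trial_average",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("C", "IC", "N")


class CapacityError(ValueError):
    """Raised when the requested trials do not fit in the available volumes."""


@dataclass
class Paradigm:
    """A realized trial schedule.

    ``onsets`` holds one ``(run, onset_s, condition)`` triple per trial, with
    onsets in seconds relative to the start of the trial's run and lying on
    multiples of the TR.
    """

    n_runs: int = 4
    volumes_per_run: int = 164
    tr: float = 2.5
    baseline_s: float = 10.0
    trials_per_condition_per_run: int = 32
    conditions: tuple = CONDITIONS
    onsets: list = field(default_factory=list)
    seed: int = 0

    @property
    def run_duration_s(self) -> float:
        return self.volumes_per_run * self.tr

    @property
    def total_duration_s(self) -> float:
        return self.n_runs * self.run_duration_s

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def onsets_for(self, condition: str) -> list[tuple[int, float]]:
        """(run, onset_s) pairs for one condition, in schedule order."""
        return [(r, t) for r, t, c in self.onsets if c == condition]

    def mean_isi_onset_to_onset(self) -> float:
        """Total acquisition duration divided by total trial count.

        This is the interval definition under which the default design gives
        a mean ISI of 4.27 s.
        """
        return self.total_duration_s / self.n_trials

    def mean_isi_gap(self) -> float:
        """Mean gap between the end of one stimulus (onset + TR) and the next
        onset, averaged over consecutive within-run pairs."""
        gaps = []
        for run in range(self.n_runs):
            times = sorted(t for r, t, _ in self.onsets if r == run)
            gaps.extend(np.diff(times) - self.tr)
        return float(np.mean(gaps)) if gaps else float("nan")


def generate_paradigm(
    n_runs: int = 4,
    volumes_per_run: int = 164,
    tr: float = 2.5,
    baseline_s: float = 10.0,
    trials_per_condition_per_run: int = 32,
    conditions: tuple = CONDITIONS,
    min_isi_s: float | None = None,
    seed: int = 0,
) -> Paradigm:
    """Randomly assign trial onsets to TR-multiple slots after the baseline.

    Onsets are drawn uniformly without replacement from the admissible slots,
    and condition labels are shuffled over the chosen slots; the schedule is
    deterministic per seed.  With ``min_isi_s`` set, only every
    ``ceil(min_isi_s / tr)``-th slot is admissible, guaranteeing an
    onset-to-onset spacing of at least ``min_isi_s`` (isolated-trial mode).
    """
    rng = np.random.default_rng(seed)
    run_duration = volumes_per_run * tr
    n_per_run = trials_per_condition_per_run * len(conditions)

    first_slot = int(np.ceil(baseline_s / tr - 1e-9))
    last_slot = volumes_per_run - 1  # stimulus occupies its own volume
    slots = np.arange(first_slot, last_slot + 1)
    if min_isi_s is not None:
        stride = int(np.ceil(min_isi_s / tr - 1e-9))
        slots = slots[::stride]
    if n_per_run > slots.size:
        raise CapacityError(
            f"{n_per_run} trials per run do not fit in {slots.size} admissible slots "
            f"(run of {run_duration:.0f} s, baseline {baseline_s:.0f} s)"
        )

    onsets: list[tuple[int, float, str]] = []
    for run in range(n_runs):
        chosen = np.sort(rng.choice(slots, size=n_per_run, replace=False))
        labels = np.repeat(np.asarray(conditions, dtype=object), trials_per_condition_per_run)
        rng.shuffle(labels)
        onsets.extend((run, float(s * tr), str(lab)) for s, lab in zip(chosen, labels))
    return Paradigm(
        n_runs=n_runs,
        volumes_per_run=volumes_per_run,
        tr=tr,
        baseline_s=baseline_s,
        trials_per_condition_per_run=trials_per_condition_per_run,
        conditions=tuple(conditions),
        onsets=onsets,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Generating parameters for one synthetic subject.

    Per trial of condition ``cond``, the event train receives an excitatory
    impulse of ``alpha[cond]`` bits at the trial onset, an inhibitory impulse
    of ``beta_frac * alpha[cond]`` bits at onset + ``t_inhib``, and a secondary
    excitatory impulse of ``gamma_frac * alpha[cond]`` bits at onset +
    ``t_second``.  Only conditions listed in ``alpha`` produce information
    deliveries (the Neutral condition is generated in the schedule but carries
    no modelled load unless given an amount).
    """

    alpha: dict = field(default_factory=lambda: {"C": 1.0, "IC": 1.3})
    ipc: IPCParams = field(default_factory=lambda: IPCParams(p=1.0, m=2.0))
    t_inhib: float = 2.5
    t_second: float = 5.0
    beta_frac: float = 0.5
    gamma_frac: float = 0.2
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(kind="none"))

    def two_state(self, condition: str) -> TwoStateParams:
        """The single-trial response of ``condition`` in the two-state
        parameterization (amplitudes referenced at T_ref and 2 T_ref)."""
        a_bits = self.alpha[condition]
        k, m = self.ipc.k, self.ipc.m
        c = self.ipc.c_loss
        t_ref = 2.5
        b_onset = c * self.beta_frac * a_bits / m
        c_onset = c * self.gamma_frac * a_bits / m
        return TwoStateParams(
            a=c * a_bits / m,
            b=b_onset * float(np.exp(k * (t_ref - self.t_inhib))),
            c_amp=c_onset * float(np.exp(k * (2 * t_ref - self.t_second))),
            k=k,
            T0=self.t_inhib,
            T1=self.t_second,
            T_ref=t_ref,
        )

    def event_train(self, onsets_s: list[float], condition: str) -> EventTrain:
        """Build the impulse train for the given trial onsets of a condition."""
        a_bits = self.alpha.get(condition, 0.0)
        exc, inh = [], []
        for t in onsets_s:
            exc.append((t, a_bits))
            if self.gamma_frac > 0:
                exc.append((t + self.t_second, self.gamma_frac * a_bits))
            if self.beta_frac > 0:
                inh.append((t + self.t_inhib, self.beta_frac * a_bits))
        return EventTrain(excitatory=sorted(exc), inhibitory=sorted(inh))


def generate_subject(
    paradigm: Paradigm,
    truth: GroundTruth,
    fine_dt: float = FINE_DT,
) -> tuple[SampledBOLD, dict]:
    """Simulate one subject: events -> IPC activity -> HRF convolution -> TR
    sampling -> noise.

    Runs are simulated independently and the sampled runs concatenated.
    Returns the sampled BOLD plus a record holding the exact generating
    parameters (for recovery tests) and the per-run activity peak.
    """
    run_vals = []
    h = hrf_kernel(truth.hrf, time_grid(DEFAULT_SUPPORT_S, fine_dt))
    x_peak = 0.0
    for run in range(paradigm.n_runs):
        grid = time_grid(paradigm.run_duration_s - fine_dt, fine_dt)
        train = EventTrain()
        for cond in paradigm.conditions:
            onsets = [t for r, t in paradigm.onsets_for(cond) if r == run]
            if truth.alpha.get(cond, 0.0) > 0 and onsets:
                train = train + truth.event_train(onsets, cond)
        x = simulate_ipc(train, truth.ipc, grid)
        x_peak = max(x_peak, float(np.max(np.abs(x.values))) if len(x) else 0.0)
        y = convolve_bold(x, h)
        run_vals.append(sample_and_noise(y, paradigm.tr, noise=None).values)

    vals = np.concatenate(run_vals)
    vals = vals + truth.noise.draw(vals.size)
    bold = SampledBOLD(tr=paradigm.tr, values=vals, t0=0.0)
    record = {
        "truth": truth,
        "paradigm_seed": paradigm.seed,
        "x_peak": x_peak,
        "n_volumes": int(vals.size),
    }
    return bold, record


def trial_average(
    y: SampledBOLD,
    paradigm: Paradigm,
    condition: str,
    window_s: float = 15.0,
) -> SampledBOLD:
    """Trial-averaged impulse response for one condition.

    For each trial onset, samples at offsets {0, TR, ..., window_s} are
    extracted and averaged across trials; a 15 s window at TR = 2.5 s yields
    exactly 7 points.  Trials whose window would cross the end of their run
    are dropped with a logged warning.
    """
    ratio = window_s / y.tr
    n_off = int(round(ratio)) + 1
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"window_s={window_s} must be a multiple of tr={y.tr}")
    segs = []
    dropped = 0
    for run, onset in paradigm.onsets_for(condition):
        i0 = int(round(onset / y.tr))
        if i0 + n_off > paradigm.volumes_per_run:
            dropped += 1
            continue
        g0 = run * paradigm.volumes_per_run + i0
        segs.append(y.values[g0 : g0 + n_off])
    if dropped:
        logger.warning(
            "trial_average(%s): dropped %d trial(s) whose %g s window crossed a run end",
            condition, dropped, window_s,
        )
    if not segs:
        raise ValueError(f"no usable trials for condition {condition!r}")
    return SampledBOLD(tr=y.tr, values=np.mean(segs, axis=0), t0=0.0)
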