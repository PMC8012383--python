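"""Synthetic howl-contour generator with per-individual vocal signatures.

The generator emulates the structure of Indian wolf howls as seen on
spectrograms: a low, slowly modulated fundamental around 422 Hz lasting
about 5.21 s, built from a small number of smooth frequency arcs, with
occasional abrupt jumps of the fundamental and fine-scale tremor.  Identity
is carried on exactly the axes that separate real individuals — baseline
pitch, modulation depth and shape, jump rate/size, and typical duration —
while recording-to-recording variation comes from per-howl pitch jitter,
session-level offsets, duration noise and white sample noise.

The ``separation`` parameter scales how far individuals sit apart relative
to the within-individual sample noise: the between-individual standard
deviation of the baseline fundamental is ``separation * within_sd``.  At
separation 0 all individuals share identical profiles and only noise
remains, so identification accuracy should collapse to chance.

Training individuals are recorded over several sessions (wolves drift in
pitch and duration from day to day), whereas each test batch comes from a
single session per individual — matching how field training libraries and
survey batches are actually collected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contours import GRID_STEP, F0Contour, write_contour
from .exceptions import HowlIdError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndividualProfile:
    """Generative parameters for one simulated wolf."""

    individual_id: str
    base_f0: float  # Hz, baseline fundamental
    duration_mean: float  # s
    duration_sd: float  # s, howl-to-howl duration spread
    arc_depth: float  # Hz, amplitude of the slow frequency modulation
    arc_count: int  # number of half-sine arcs per howl
    jump_rate: float  # expected abrupt-jump events per howl
    jump_size: float  # Hz, magnitude of a jump excursion
    within_sd: float  # Hz, white noise per 0.1 s sample
    f0_jitter_sd: float = 0.0  # Hz, per-howl baseline offset
    arc_shape: float = 1.0  # time-warp exponent of the modulation arcs
    terminal_drop: float = 0.0  # Hz, rapid pitch fall on the final sample

    def __post_init__(self) -> None:
        if self.base_f0 <= 0:
            raise HowlIdError("base_f0 must be positive")
        if self.duration_mean <= 0:
            raise HowlIdError("duration_mean must be positive")
        if self.within_sd < 0:
            raise HowlIdError("within_sd must be non-negative")


@dataclass
class SyntheticConfig:
    """Study-design parameters for a simulated training/test corpus.

    Defaults mirror the population this generator emulates: mean
    fundamental 422 Hz, mean duration 5.21 s, five training individuals
    with ten howls each recorded across three sessions, and a disjoint
    four-individual test batch of five howls each from single sessions.
    """

    n_individuals: int = 5
    howls_per_individual: int = 10
    n_test_individuals: int = 4
    test_howls_per_individual: int = 5
    population_f0_mean: float = 422.0
    population_duration_mean: float = 5.21
    separation: float = 3.0
    within_sd: float = 3.0
    f0_jitter_sd: float = 0.6
    session_sd: float = 1.5
    session_duration_sd: float = 0.2
    n_sessions: int = 3
    duration_sd: float = 0.05
    session_depth_log_sd: float = 0.12
    session_rate_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise HowlIdError("need at least 2 training individuals")
        if self.howls_per_individual < 3:
            raise HowlIdError(
                "each training individual needs at least 3 howls"
            )
        if self.separation < 0:
            raise HowlIdError("separation must be non-negative")


@dataclass
class SyntheticDataset:
    """Labelled synthetic corpus with disjoint training and test howls."""

    train: list[F0Contour]
    test: list[F0Contour]
    train_profiles: list[IndividualProfile]
    test_profiles: list[IndividualProfile]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore

    @property
    def train_labels(self) -> dict[str, str]:
        return {c.howl_id: c.individual_label for c in self.train}

    @property
    def test_labels(self) -> dict[str, str]:
        return {c.howl_id: c.individual_label for c in self.test}


# Between-individual spread per unit separation on each identity axis,
# sized against that axis's within-individual howl-level variation so that
# "separation" means between-SD over within-SD throughout: baseline f0
# varies within an individual by ~within_sd per howl (jitter + session
# drift), durations by ~0.3 s, arc depth by its 10% per-howl jitter, jump
# counts by Poisson noise (~sqrt(rate)), jump magnitude by its 10% jitter.
_F0_SPREAD_PER_SEP = 1.0  # x within_sd
_DURATION_SPREAD_PER_SEP = 0.4  # s
_ARC_DEPTH_SPREAD_PER_SEP = 8.0  # Hz
_ARC_COUNT_SPREAD_PER_SEP = 0.5
_ARC_SHAPE_SPREAD_PER_SEP = 0.25  # log-scale warp of the arc peak position
_JUMP_RATE_SPREAD_PER_SEP = 0.08
_JUMP_SIZE_SPREAD_PER_SEP = 1.0  # Hz
#: per-event magnitude spread (log scale): most breaks sit between 25 and
#: 100 Hz with a tail above 100, matching the graded abrupt-change ladder
_JUMP_MAG_LOG_SD = 0.25
#: breaks fall in the first part of the howl (onset instability)
_ONSET_FRACTION = 0.15
#: linear amplitude decay of the modulation arcs over the howl
_ARC_DECAY = 0.2
#: downward drift of the contour over the howl, as a fraction of depth
_TERMINAL_FALL_FRACTION = 0.2
#: terminal pitch fall = 0.9 x arc depth + an individual excess (Hz); the
#: fall then always undercuts the arc trough by at least the excess, so
#: the contour minimum sits firmly on the last sample, while whether the
#: final step crosses the 100 Hz threshold depends on the individual
_TERMINAL_EXCESS_MEAN = 32.0
_TERMINAL_EXCESS_SPREAD_PER_SEP = 8.0
_TERMINAL_DROP_HOWL_JITTER = 1.0
_TERMINAL_DROP_SESSION_SD = 3.0

_ARC_DEPTH_MEAN = 80.0  # Hz
_ARC_COUNT_MEAN = 2
_JUMP_RATE_MEAN = 2.0
_JUMP_SIZE_MEAN = 30.0  # Hz


def generate_profiles(
    config: SyntheticConfig,
    rng: np.random.Generator,
    n: int | None = None,
    prefix: str = "W",
) -> list[IndividualProfile]:
    """Draw per-individual parameters around the population means.

    All identity-bearing parameters have between-individual spread
    proportional to ``config.separation``; at separation 0 every profile
    equals the population mean and only the noise fields differ from zero.
    """
    if config.separation < 0:
        raise HowlIdError("separation must be non-negative")
    if n is None:
        n = config.n_individuals
    sep = config.separation
    w = config.within_sd
    profiles = []
    for i in range(n):
        base_f0 = rng.normal(
            config.population_f0_mean, _F0_SPREAD_PER_SEP * sep * w
        )
        duration_mean = rng.normal(
            config.population_duration_mean, _DURATION_SPREAD_PER_SEP * sep
        )
        arc_depth = max(
            rng.normal(_ARC_DEPTH_MEAN, _ARC_DEPTH_SPREAD_PER_SEP * sep), 5.0
        )
        arc_count = int(
            np.clip(
                round(rng.normal(_ARC_COUNT_MEAN, _ARC_COUNT_SPREAD_PER_SEP * sep)),
                1,
                3,
            )
        )
        jump_rate = max(
            rng.normal(_JUMP_RATE_MEAN, _JUMP_RATE_SPREAD_PER_SEP * sep), 0.0
        )
        jump_size = max(
            rng.normal(_JUMP_SIZE_MEAN, _JUMP_SIZE_SPREAD_PER_SEP * sep), 40.0
        )
        arc_shape = float(
            np.clip(
                np.exp(rng.normal(0.0, _ARC_SHAPE_SPREAD_PER_SEP * sep)),
                0.4,
                2.5,
            )
        )
        terminal_excess = max(
            rng.normal(
                _TERMINAL_EXCESS_MEAN, _TERMINAL_EXCESS_SPREAD_PER_SEP * sep
            ),
            15.0,
        )
        terminal_drop = 0.9 * arc_depth + terminal_excess
        profiles.append(
            IndividualProfile(
                individual_id=f"{prefix}{i + 1:02d}",
                base_f0=max(base_f0, 50.0),
                duration_mean=max(duration_mean, 1.0),
                duration_sd=config.duration_sd,
                arc_depth=arc_depth,
                arc_count=arc_count,
                jump_rate=jump_rate,
                jump_size=jump_size,
                within_sd=config.within_sd,
                f0_jitter_sd=config.f0_jitter_sd,
                arc_shape=arc_shape,
                terminal_drop=terminal_drop,
            )
        )
    return profiles


def generate_howl(
    profile: IndividualProfile,
    rng: np.random.Generator,
    step: float = GRID_STEP,
    howl_id: str = "howl",
    f0_offset: float = 0.0,
    duration_offset: float = 0.0,
    depth_scale: float = 1.0,
    rate_scale: float = 1.0,
    drop_offset: float = 0.0,
    session_date: str | None = None,
) -> F0Contour:
    """Synthesise one howl contour directly on the sampling grid.

    f0(t) = baseline + mean-centred half-sine arcs (time-warped by the
    individual's ``arc_shape``) + Poisson-count jump excursions + white
    noise, clipped positive.  The arc component is centred so the baseline
    is also the howl's expected mean frequency; jumps are brief excursions
    (one to three samples) that produce step discontinuities on entry and
    exit without shifting the howl-level mean much.
    """
    duration = max(
        profile.duration_mean
        + duration_offset
        + profile.duration_sd * rng.standard_normal(),
        2.5 * step,
    )
    n = int(np.floor(duration / step + 1e-9)) + 1
    times = step * np.arange(n)

    base = (
        profile.base_f0
        + f0_offset
        + profile.f0_jitter_sd * rng.standard_normal()
    )
    depth = (
        profile.arc_depth
        * depth_scale
        * (1.0 + 0.015 * rng.standard_normal())
    )
    tau_lin = times / duration
    tau = tau_lin ** profile.arc_shape
    # slight amplitude decay toward the end of the howl; with several arcs
    # this makes the first peak the global maximum, so the extremum
    # positions are stable against tremor
    envelope = 1.0 - _ARC_DECAY * tau_lin
    arc = depth * envelope * np.sin(np.pi * profile.arc_count * tau)
    # terminal fall: howls drift slightly downward and end low, which
    # anchors the position of the contour minimum; scaled by depth so an
    # unmodulated profile stays flat
    arc = arc - _TERMINAL_FALL_FRACTION * depth * tau_lin
    freqs = base + arc - arc.mean()

    # onset instability: brief upward breaks concentrated in the first
    # part of the howl while phonation settles, as seen on spectrograms;
    # the contour starts low there, so breaks rise toward the mean level
    # and register in the abrupt-change counters without displacing the
    # howl's extrema
    n_jumps = rng.poisson(profile.jump_rate * rate_scale)
    onset_end = max(2, int(round(_ONSET_FRACTION * n)))
    for _ in range(n_jumps):
        if n < 3:
            break
        pos = int(rng.integers(1, min(onset_end, n - 1)))
        length = int(rng.integers(1, 3))
        mag = profile.jump_size * float(
            np.exp(_JUMP_MAG_LOG_SD * rng.standard_normal())
        )
        freqs[pos : pos + length] += mag

    # rapid terminal pitch fall on the last sample, as howls trail off
    if profile.terminal_drop > 0:
        freqs[-1] -= (
            profile.terminal_drop
            + drop_offset
            + _TERMINAL_DROP_HOWL_JITTER * rng.standard_normal()
        )

    if profile.within_sd > 0:
        freqs = freqs + profile.within_sd * rng.standard_normal(n)
    freqs = np.clip(freqs, 1.0, None)

    return F0Contour(
        howl_id=howl_id,
        times=times,
        freqs=freqs,
        individual_label=profile.individual_id,
        session_date=session_date,
        t_start=0.0,
        t_end=duration,
    )


def _generate_individual_howls(
    profile: IndividualProfile,
    config: SyntheticConfig,
    rng: np.random.Generator,
    n_howls: int,
    n_sessions: int,
    date_prefix: str,
) -> list[F0Contour]:
    # day-to-day (session) state: pitch and duration offsets plus
    # multiplicative modulation-depth and break-intensity factors — the
    # across-day component of within-individual variation
    sessions = [
        (
            rng.normal(0.0, config.session_sd),
            rng.normal(0.0, config.session_duration_sd),
            float(np.exp(rng.normal(0.0, config.session_depth_log_sd))),
            float(np.exp(rng.normal(0.0, config.session_rate_log_sd))),
            rng.normal(0.0, _TERMINAL_DROP_SESSION_SD),
        )
        for _ in range(n_sessions)
    ]
    howls = []
    for j in range(n_howls):
        s = j % n_sessions
        f0_off, dur_off, depth_scale, rate_scale, drop_off = sessions[s]
        howls.append(
            generate_howl(
                profile,
                rng,
                howl_id=f"{profile.individual_id}_h{j + 1:02d}",
                f0_offset=f0_off,
                duration_offset=dur_off,
                depth_scale=depth_scale,
                rate_scale=rate_scale,
                drop_offset=drop_off,
                session_date=f"{date_prefix}-{s + 1:02d}",
            )
        )
    return howls


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a labelled training corpus plus a disjoint test batch.

    Test howls come from individuals never seen in training, mirroring the
    survey situation where unknown wolves must be counted and told apart
    without having contributed to the model.  Deterministic under a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    train_profiles = generate_profiles(
        config, rng, config.n_individuals, prefix="TRN"
    )
    test_profiles = generate_profiles(
        config, rng, config.n_test_individuals, prefix="TST"
    )
    train: list[F0Contour] = []
    for p in train_profiles:
        train.extend(
            _generate_individual_howls(
                p,
                config,
                rng,
                config.howls_per_individual,
                config.n_sessions,
                "2016-01",
            )
        )
    test: list[F0Contour] = []
    for p in test_profiles:
        test.extend(
            _generate_individual_howls(
                p, config, rng, config.test_howls_per_individual, 1, "2016-02"
            )
        )
    return SyntheticDataset(
        train=train,
        test=test,
        train_profiles=train_profiles,
        test_profiles=test_profiles,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write contour files and the metadata table in the package dialect.

    Layout: ``contours/<howl_id>.csv`` plus ``metadata.csv`` with columns
    howl_id, individual_label, session_date, subset; the generating seed is
    recorded in the metadata header comment line of ``seed.txt``.
    """
    outdir = Path(outdir)
    (outdir / "contours").mkdir(parents=True, exist_ok=True)
    rows = ["howl_id,individual_label,session_date,subset"]
    for subset, contours in (("train", dataset.train), ("test", dataset.test)):
        for c in contours:
            write_contour(c, outdir / "contours" / f"{c.howl_id}.csv")
            rows.append(
                f"{c.howl_id},{c.individual_label},{c.session_date},{subset}"
            )
    (outdir / "metadata.csv").write_text("\n".join(rows) + "\n")
    if dataset.config is not None:
        (outdir / "seed.txt").write_text(f"{dataset.config.seed}\n")
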