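"""Analysis mathematics for aptamer validation assays.

Covers the two wet-lab readouts used to judge a matured aptamer:

* biolayer interferometry (BLI): simulation and global 1:1 Langmuir
  fitting of association/dissociation sensorgrams to recover kon,
  koff and the dissociation constant Kd = koff/kon;
* the molecular-beacon fluorescence aptasensor: beacon design
  (stem-loop complementary to an aptamer region, fluorophore/quencher
  labelled), the fluorescence reduction rate y = (F0 - F)/F0 * 100%,
  linear calibration against analyte concentration, the 3-sigma limit
  of detection, and a selectivity summary.

Concentrations are in nM at the interface; they are converted to molar
only inside the rate equations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .sequences import NucleotideSequence, reverse_complement

NM_TO_M = 1e-9


# ---------------------------------------------------------------------------
# sensorgrams

@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the phases recorded in a sensorgram.

    The instrument protocol has five dips (equilibration, aptamer
    loading, wash, association, dissociation); only the last two carry
    kinetic information, so the simulated trace keeps a short baseline
    followed by association and dissociation.
    """

    baseline: float = 120.0
    association: float = 120.0
    dissociation: float = 120.0

    def __post_init__(self) -> None:
        if min(self.baseline, self.association, self.dissociation) < 0:
            raise ValueError("phase durations must be non-negative")


@dataclass
class Sensorgram:
    """A BLI time series (s, nm) for one analyte concentration."""

    time: np.ndarray
    response: np.ndarray
    schedule: PhaseSchedule
    concentration: float  # nM

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def phase_masks(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        t0 = self.schedule.baseline
        t1 = t0 + self.schedule.association
        return self.time < t0, (self.time >= t0) & (self.time < t1), self.time >= t1


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concentration: float,
    schedule: PhaseSchedule = PhaseSchedule(),
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    dt: float = 1.0,
) -> Sensorgram:
    """Ideal 1:1 Langmuir sensorgram with optional Gaussian noise.

    Association follows R(t) = Req (1 - exp(-(kon C + koff) t)) with
    Req = Rmax C / (C + Kd); dissociation decays exponentially with
    koff from the association end-point.
    """
    if min(kon, koff, rmax) <= 0:
        raise ValueError("kon, koff and rmax must be positive")
    if concentration < 0 or noise_sd < 0:
        raise ValueError("concentration and noise_sd must be non-negative")
    c = concentration * NM_TO_M
    kd = koff / kon
    req = rmax * c / (c + kd) if c > 0 else 0.0
    kobs = kon * c + koff

    t = np.arange(0.0, schedule.baseline + schedule.association + schedule.dissociation, dt)
    r = np.zeros_like(t)
    t0 = schedule.baseline
    t1 = t0 + schedule.association
    assoc = (t >= t0) & (t < t1)
    r[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - t0)))
    r_end = req * (1.0 - np.exp(-kobs * schedule.association))
    dissoc = t >= t1
    r[dissoc] = r_end * np.exp(-koff * (t[dissoc] - t1))
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(time=t, response=r, schedule=schedule, concentration=concentration)


@dataclass(frozen=True)
class KineticFit:
    """Globally fitted 1:1 binding kinetics."""

    kon: float          # 1/(M s)
    koff: float         # 1/s
    kd_nM: float        # koff/kon, in nM
    rmax: float         # nm
    residual_norm: float
    converged: bool
    n_starts: int

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.rmax <= 0:
            raise ValueError("fitted rates must be positive")
        expected = self.koff / self.kon / NM_TO_M
        if abs(expected - self.kd_nM) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("kd must equal koff/kon")


def _model_response(theta: np.ndarray, grams: Sequence[Sensorgram]) -> np.ndarray:
    kon, koff, rmax = np.exp(theta)
    out = []
    for g in grams:
        c = g.concentration * NM_TO_M
        kd = koff / kon
        req = rmax * c / (c + kd) if c > 0 else 0.0
        kobs = kon * c + koff
        t0 = g.schedule.baseline
        t1 = t0 + g.schedule.association
        r = np.zeros_like(g.time)
        assoc = (g.time >= t0) & (g.time < t1)
        r[assoc] = req * (1.0 - np.exp(-kobs * (g.time[assoc] - t0)))
        r_end = req * (1.0 - np.exp(-kobs * g.schedule.association))
        dissoc = g.time >= t1
        r[dissoc] = r_end * np.exp(-koff * (g.time[dissoc] - t1))
        out.append(r)
    return np.concatenate(out)


def fit_kinetics_1to1(sensorgrams: Sequence[Sensorgram]) -> KineticFit:
    """Global nonlinear least squares over all concentrations.

    kon, koff and Rmax are shared across traces; fitting runs from a
    small multi-start grid in log-parameter space and keeps the best
    optimum. Non-convergence of every start raises rather than
    returning a silent garbage fit.
    """
    if len(sensorgrams) < 2:
        raise ValueError("need sensorgrams at >= 2 analyte concentrations")
    obs = np.concatenate([g.response for g in sensorgrams])
    rmax0 = max(1e-6, float(np.nanmax(obs)))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model_response(theta, sensorgrams) - obs

    best = None
    n_starts = 0
    for kon0 in (1e4, 1e5, 1e6):
        for koff0 in (1e-3, 1e-2, 1e-1):
            n_starts += 1
            theta0 = np.log([kon0, koff0, rmax0 * 1.5])
            try:
                sol = optimize.least_squares(
                    residuals, theta0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                    max_nfev=20000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise RuntimeError("kinetic fit failed to converge from any start")
    kon, koff, rmax = np.exp(best.x)
    return KineticFit(
        kon=float(kon),
        koff=float(koff),
        kd_nM=float(koff / kon / NM_TO_M),
        rmax=float(rmax),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
        n_starts=n_starts,
    )


# ---------------------------------------------------------------------------
# molecular beacons

@dataclass(frozen=True)
class BeaconDesign:
    """A stem-loop molecular beacon complementary to an aptamer region."""

    sequence: str
    loop_length: int
    stem_length: int
    target_region: Tuple[int, int]  # 1-based inclusive region of the aptamer
    aptamer_id: str
    fluorophore: str = "FAM"   # 5' label
    quencher: str = "BHQ1"     # 3' label

    @property
    def loop(self) -> str:
        return self.sequence[self.stem_length : self.stem_length + self.loop_length]

    @property
    def name(self) -> str:
        return f"MB-{self.loop_length}"


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _max_duplex_match(a: str, b: str) -> int:
    """Best count of WC pairs when sliding a against reversed b."""
    best = 0
    rb = b[::-1]
    for off in range(-(len(rb) - 1), len(a)):
        count = 0
        for k in range(len(rb)):
            pos = off + k
            if 0 <= pos < len(a) and (a[pos], rb[k]) in _WC:
                count += 1
        best = max(best, count)
    return best


def design_beacon(
    aptamer: NucleotideSequence,
    loop_length: int,
    stem_length: int = 5,
    anchor: str = "3prime",
) -> BeaconDesign:
    """Design a beacon whose loop hybridises a terminal aptamer region.

    The loop is the reverse complement of the chosen region (default:
    the 3' terminus, keeping the beacon away from the 5'-proximal bases
    typically engaged in target binding); the stem appends
    ``stem_length`` mutually reverse-complementary bases chosen not to
    pair appreciably with the loop.
    """
    n = len(aptamer)
    if loop_length < 1 or loop_length > n:
        raise ValueError("loop region out of aptamer bounds")
    if anchor == "3prime":
        region = (n - loop_length + 1, n)
    elif anchor == "5prime":
        region = (1, loop_length)
    else:
        raise ValueError("anchor must be '5prime' or '3prime'")
    target = aptamer.bases[region[0] - 1 : region[1]]
    loop = reverse_complement(target)

    # deterministic stem search over GC-only candidates
    from itertools import product

    for combo in product("GC", repeat=stem_length):
        stem5 = "".join(combo)
        if _max_duplex_match(loop, stem5) >= max(3, stem_length - 1):
            continue
        stem3 = reverse_complement(stem5)
        seq = stem5 + loop + stem3
        # the two termini must close into the stem, not into the loop
        return BeaconDesign(
            sequence=seq,
            loop_length=loop_length,
            stem_length=stem_length,
            target_region=region,
            aptamer_id=aptamer.id,
        )
    raise ValueError("no stem avoids pairing with the loop; shorten the stem")


def beacon_panel(
    aptamer: NucleotideSequence,
    loop_lengths: Sequence[int] = (10, 15, 20, 25),
    stem_length: int = 5,
) -> List[BeaconDesign]:
    return [design_beacon(aptamer, L, stem_length) for L in loop_lengths]


# ---------------------------------------------------------------------------
# fluorescence analytics

def reduction_rate(f0: float, f: float) -> float:
    """Fluorescence reduction y = (F0 - F)/F0 * 100 (percent).

    Negative rates (signal above blank) are legal but flagged with a
    warning.
    """
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    y = (f0 - f) / f0 * 100.0
    if y < 0:
        warnings.warn(f"negative reduction rate ({y:.2f}%): F exceeds F0")
    return y


@dataclass(frozen=True)
class CalibrationFit:
    """Linear calibration of reduction rate vs concentration."""

    slope: float       # % per nM
    intercept: float   # %
    r_squared: float
    lod_nM: Optional[float]  # 3 sigma(blank) / slope, when blanks supplied
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def fit_calibration(
    concentrations: Sequence[float],
    rates: Sequence[float],
    blank_rates: Optional[Sequence[float]] = None,
) -> CalibrationFit:
    """Ordinary least squares line through (C, y) points.

    The limit of detection is 3 * SD(blank rates) / slope and needs
    blank replicates; the published figure for such an assay is not
    recomputable without them.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate calibration: all concentrations equal")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    lod = None
    if blank_rates is not None:
        blanks = np.asarray(blank_rates, dtype=float)
        if blanks.size < 2:
            raise ValueError("need >= 2 blank replicates for the LOD")
        if res.slope <= 0:
            raise ValueError("LOD undefined for non-positive slope")
        lod = float(3.0 * np.std(blanks, ddof=1) / res.slope)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        lod_nM=lod,
        n_points=int(x.size),
    )


# ---------------------------------------------------------------------------
# selectivity

@dataclass(frozen=True)
class SelectivityReport:
    ranked: Tuple[Tuple[str, float], ...]  # (name, rate), descending
    target_name: str
    ratio_to_worst_interferent: Optional[float]
    target_ranked_first: bool


def selectivity_table(
    target_rate: float,
    interferent_rates: Dict[str, float],
    target_name: str = "target",
) -> SelectivityReport:
    """Rank the target against interferents by reduction rate.

    The headline number is the ratio of the target's rate to the
    largest interferent rate (undefined, and flagged None, when no
    interferent responds).
    """
    if not interferent_rates:
        raise ValueError("interferent map is empty")
    entries = [(target_name, float(target_rate))] + [
        (k, float(v)) for k, v in interferent_rates.items()
    ]
    entries.sort(key=lambda kv: (-kv[1], kv[0]))
    worst = max(interferent_rates.values())
    ratio = None if worst == 0 else float(target_rate / worst)
    if ratio is None:
        warnings.warn("all interferent rates are zero; selectivity ratio undefined")
    return SelectivityReport(
        ranked=tuple(entries),
        target_name=target_name,
        ratio_to_worst_interferent=ratio,
        target_ranked_first=entries[0][0] == target_name,
    )
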