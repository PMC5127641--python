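"""Biolayer-interferometry kinetics and related biophysics.

Binding of each inhibitor to each of the six pro-survival BCL2 homologs
(Bcl-2, Bcl-xL, Bcl-w, Mcl-1, Bfl-1, Bcl-B) is measured by BLI titration
and fit globally to a 1:1 Langmuir model, giving kon, koff and
KD = koff/kon. Interactions too weak to produce signal are censored
(KD > highest tested concentration), and the specificity of an inhibitor
is the smallest off-target/on-target KD ratio, reported as a lower bound
when the limiting off-target is censored. A fraction-folded normalization
for CD denaturation scans rounds out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import least_squares

HOMOLOGS = ("Bcl-2", "Bcl-xL", "Bcl-w", "Mcl-1", "Bfl-1", "Bcl-B")

KON_BOUNDS = (1e2, 1e8)   # M^-1 s^-1
KOFF_BOUNDS = (1e-7, 1.0)  # s^-1


@dataclass
class KineticTrace:
    """One BLI phase at one analyte concentration."""

    time: np.ndarray           # seconds, strictly increasing, from phase start
    signal: np.ndarray         # response units
    concentration: float       # molar analyte concentration
    phase: str                 # "association" or "dissociation"
    pair_id: tuple = ("", "")  # (inhibitor, homolog)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase not in ("association", "dissociation"):
            raise ValueError("phase must be 'association' or 'dissociation'")


@dataclass
class KineticFit:
    kon: float                 # M^-1 s^-1
    koff: float                # s^-1
    kd: float                  # molar, koff/kon
    rmax: float                # response units
    residual_rms: float
    censored: bool = False
    censor_bound: float | None = None   # molar
    n_concentrations: int = 0
    offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.censored and self.censor_bound is None:
            raise ValueError("censored fits must carry a censor bound")


@dataclass
class SpecificityProfile:
    """KD of one inhibitor against the pro-survival panel."""

    inhibitor: str
    on_target: str
    kd: dict            # homolog -> molar KD (censored entries hold the bound)
    censored: dict      # homolog -> bool

    def __post_init__(self) -> None:
        if self.on_target not in self.kd:
            raise ValueError("profile lacks the on-target KD")


@dataclass
class FoldSpecificity:
    fold: float
    is_lower_bound: bool
    limiting_homolog: str

    def __str__(self) -> str:
        prefix = ">= " if self.is_lower_bound else ""
        return f"{prefix}{self.fold:.0f}-fold vs {self.limiting_homolog}"


# ---------------------------------------------------------------------------
# 1:1 Langmuir model


def model_association(kon: float, koff: float, rmax: float, concentration: float,
                      t) -> np.ndarray:
    """1:1 association: Rmax * C/(C+KD) * (1 - exp(-(kon*C + koff) t))."""
    if kon <= 0 or koff <= 0 or rmax <= 0 or concentration <= 0:
        raise ValueError("kinetic parameters and concentration must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    kd = koff / kon
    kobs = kon * concentration + koff
    return rmax * concentration / (concentration + kd) * (1.0 - np.exp(-kobs * t))


def model_dissociation(r0: float, koff: float, t) -> np.ndarray:
    """1:1 dissociation: R0 * exp(-koff t)."""
    if r0 < 0:
        raise ValueError("R0 must be non-negative")
    if koff <= 0:
        raise ValueError("koff must be positive")
    return r0 * np.exp(-koff * np.asarray(t, dtype=float))


def _trace_noise(trace: KineticTrace) -> float:
    """Robust noise estimate from first differences (signal trend cancels)."""
    d = np.diff(trace.signal)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _predict(theta: np.ndarray, traces: list[KineticTrace],
             assoc_end: dict, offsets: np.ndarray | None) -> np.ndarray:
    kon, koff, rmax = 10.0 ** theta[:3]
    out = []
    for i, tr in enumerate(traces):
        if tr.phase == "association":
            y = model_association(kon, koff, rmax, tr.concentration, tr.time)
        else:
            t_end = assoc_end.get(tr.concentration)
            if t_end is not None:
                r0 = float(model_association(kon, koff, rmax, tr.concentration,
                                             np.array([t_end]))[0])
            else:  # no paired association phase: assume equilibrium was reached
                kd = koff / kon
                r0 = rmax * tr.concentration / (tr.concentration + kd)
            y = model_dissociation(r0, koff, tr.time)
        if offsets is not None:
            y = y + offsets[i]
        out.append(y)
    return np.concatenate(out)


def fit_titration(traces: list[KineticTrace], noise_floor_k: float = 3.0,
                  fit_offsets: bool = False, seed: int = 0,
                  kon_bounds: tuple = KON_BOUNDS,
                  koff_bounds: tuple = KOFF_BOUNDS) -> KineticFit:
    """Global 1:1 fit of a multi-concentration titration.

    kon, koff and Rmax are shared across every trace; dissociation phases
    start from the response the paired association phase reached at its
    final time point. Initialization scans a log-spaced (kon, koff) grid
    and the best converged fit is returned. With ``fit_offsets`` a small
    per-trace additive offset is estimated as a nuisance parameter.

    If the largest observed signal is below ``noise_floor_k`` times the
    trace noise estimate, no binding is measurable and a censored fit is
    returned with the highest tested concentration as the KD bound.
    """
    if not traces:
        raise ValueError("no traces supplied")
    concentrations = sorted({tr.concentration for tr in traces})
    if len(concentrations) < 2:
        warnings.warn("single-concentration titration: fit is poorly constrained")

    noise = max(max(_trace_noise(tr) for tr in traces), 1e-12)
    # sustained response, not a single noisy point: mean of the last tenth
    # of each association phase (or first tenth of a dissociation phase)
    plateaus = []
    for tr in traces:
        n = max(1, tr.signal.size // 10)
        seg = tr.signal[-n:] if tr.phase == "association" else tr.signal[:n]
        plateaus.append(abs(float(np.mean(seg))))
    max_signal = max(float(np.max(np.abs(tr.signal))) for tr in traces)
    if max(plateaus) < noise_floor_k * noise:
        return KineticFit(
            kon=float("nan"), koff=float("nan"), kd=float("nan"),
            rmax=float("nan"), residual_rms=float(np.std(
                np.concatenate([tr.signal for tr in traces]))),
            censored=True, censor_bound=max(concentrations),
            n_concentrations=len(concentrations),
        )

    assoc_end = {tr.concentration: tr.time[-1]
                 for tr in traces if tr.phase == "association"}
    y_obs = np.concatenate([tr.signal for tr in traces])
    n_off = len(traces) if fit_offsets else 0

    def residuals(theta):
        offs = theta[3:] if fit_offsets else None
        return _predict(theta[:3], traces, assoc_end, offs) - y_obs

    lo = [np.log10(kon_bounds[0]), np.log10(koff_bounds[0]), np.log10(max_signal) - 3]
    hi = [np.log10(kon_bounds[1]), np.log10(koff_bounds[1]), np.log10(max_signal) + 3]
    if fit_offsets:
        lo += [-0.2 * max_signal] * n_off
        hi += [0.2 * max_signal] * n_off

    best = None
    kon_grid = np.linspace(np.log10(kon_bounds[0]) + 1, np.log10(kon_bounds[1]) - 1, 4)
    koff_grid = np.linspace(np.log10(koff_bounds[0]) + 1, np.log10(koff_bounds[1]) - 1, 4)
    for lk_on, lk_off in product(kon_grid, koff_grid):
        x0 = np.array([lk_on, lk_off, np.log10(max_signal)] + [0.0] * n_off)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                x_scale="jac", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("titration fit failed to converge from any start")

    kon, koff, rmax = 10.0 ** best.x[:3]
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    offsets = {}
    if fit_offsets:
        offsets = {i: float(v) for i, v in enumerate(best.x[3:])}
    return KineticFit(kon=kon, koff=koff, kd=koff / kon, rmax=rmax,
                      residual_rms=rms, censored=False,
                      n_concentrations=len(concentrations), offsets=offsets)


# ---------------------------------------------------------------------------
# specificity


def specificity_fold(profile: SpecificityProfile) -> FoldSpecificity:
    """Smallest off-target/on-target KD ratio across the panel.

    Censored off-targets contribute bound/KD_on; when the minimizing term
    is censored the fold is itself only a lower bound ("at least N-fold").
    """
    if profile.censored.get(profile.on_target, False):
        raise ValueError("on-target KD is censored; specificity undefined")
    kd_on = profile.kd[profile.on_target]
    off = [(h, kd) for h, kd in profile.kd.items() if h != profile.on_target]
    if not off:
        raise ValueError("no off-target entries in profile")
    folds = [(kd / kd_on, h) for h, kd in off]
    fold, homolog = min(folds)
    return FoldSpecificity(fold=fold,
                           is_lower_bound=bool(profile.censored.get(homolog, False)),
                           limiting_homolog=homolog)


def profile_from_fits(inhibitor: str, on_target: str,
                      fits: dict) -> SpecificityProfile:
    """Assemble a specificity profile from per-homolog titration fits.

    Censored fits contribute their censor bound as the KD entry, so the
    resulting fold-specificity is a lower bound whenever a censored
    off-target is the limiting one.
    """
    kd, censored = {}, {}
    for homolog, fit in fits.items():
        if fit.censored:
            kd[homolog] = fit.censor_bound
            censored[homolog] = True
        else:
            kd[homolog] = fit.kd
            censored[homolog] = False
    return SpecificityProfile(inhibitor=inhibitor, on_target=on_target,
                              kd=kd, censored=censored)


# ---------------------------------------------------------------------------
# CD denaturation


def fraction_folded(signal, folded_baseline, unfolded_baseline) -> np.ndarray:
    """Normalize a CD-222 nm denaturation scan to fraction folded.

    f = (signal - unfolded) / (folded - unfolded), clipped to [0, 1].
    Baselines may be scalars or per-point arrays (sloping baselines).
    """
    signal = np.asarray(signal, dtype=float)
    folded = np.broadcast_to(np.asarray(folded_baseline, dtype=float), signal.shape)
    unfolded = np.broadcast_to(np.asarray(unfolded_baseline, dtype=float), signal.shape)
    span = folded - unfolded
    if np.any(span == 0):
        raise ValueError("folded and unfolded baselines coincide")
    return np.clip((signal - unfolded) / span, 0.0, 1.0)


# ---------------------------------------------------------------------------
# CSV interface (long format: pair_id fields, phase, conc_M, time_s, signal)


def write_traces_csv(traces: list[KineticTrace], path) -> None:
    import pandas as pd

    rows = []
    for tr in traces:
        for t, s in zip(tr.time, tr.signal):
            rows.append((tr.pair_id[0], tr.pair_id[1], tr.phase,
                         tr.concentration, t, s))
    pd.DataFrame(rows, columns=["inhibitor", "homolog", "phase", "conc_M",
                                "time_s", "signal"]).to_csv(path, index=False)


def read_traces_csv(path) -> list[KineticTrace]:
    import pandas as pd

    df = pd.read_csv(path)
    traces = []
    keys = ["inhibitor", "homolog", "phase", "conc_M"]
    for (inhib, homolog, phase, conc), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_s")
        traces.append(KineticTrace(
            time=grp["time_s"].to_numpy(), signal=grp["signal"].to_numpy(),
            concentration=float(conc), phase=phase, pair_id=(inhib, homolog)))
    return traces
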