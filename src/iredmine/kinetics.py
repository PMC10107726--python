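"""Plate-reader NAD(P)H-depletion kinetics: initial rates and heat maps.

A well's absorbance at 340 nm falls linearly while the enzyme consumes
NAD(P)H and plateaus once the cofactor is exhausted. The initial rate is
the least-squares slope over an early window of the trace, converted to a
concentration rate with the NAD(P)H molar extinction coefficient
(6220 M^-1 cm^-1 at 340 nm) and the optical path length:

    rate [umol/mL/min == mM/min] = -slope [AU/min] / (epsilon * l) * 1000

Net enzyme activity subtracts matched controls (empty-plasmid lysate and
lysate-free reactions) measured under the same (substrate, cofactor, pH)
condition. Negative net rates are floored at zero and flagged as
below-background, with the raw value retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: NAD(P)H molar extinction coefficient at 340 nm, M^-1 cm^-1.
EPSILON_NADPH = 6220.0

#: Enzyme labels treated as controls by default.
DEFAULT_CONTROL_ENZYMES = ("empty_plasmid", "no_lysate")

PLATE_COLUMNS = [
    "well", "enzyme", "substrate", "cofactor", "pH", "replicate",
    "time_min", "a340",
]


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A timestamped A340 series for one well/replicate."""

    well: str
    enzyme: str
    substrate: str
    cofactor: str
    pH: float
    replicate: int
    times: np.ndarray
    a340: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a340", a)
        if t.size != a.size:
            raise ValueError("times and a340 must have the same length")
        if t.size < 5:
            raise ValueError("a trace needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("a340 must be finite")

    @property
    def condition(self):
        return (self.enzyme, self.substrate, self.cofactor, self.pH)


@dataclass(frozen=True)
class RateResult:
    """Initial rate for one condition (per replicate or aggregated)."""

    enzyme: str
    substrate: str
    cofactor: str
    pH: float
    slope: float  # AU/min, <= 0 for depletion
    rate: float  # umol/mL/min (mM/min), positive for depletion
    fit_window: tuple  # (start index, end index) inclusive
    r2: float
    path_length: float
    n_replicates: int = 1
    net_rate: float | None = None
    raw_net: float | None = None
    below_background: bool = False

    @property
    def condition(self):
        return (self.enzyme, self.substrate, self.cofactor, self.pH)


def _linfit(t: np.ndarray, y: np.ndarray):
    """Least-squares slope and R^2; a perfect constant fit has R^2 = 1."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-18 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), min(r2, 1.0)


def fit_initial_rate(
    trace: AbsorbanceTrace,
    min_points: int = 5,
    early_fraction: float = 0.3,
    r2_threshold: float = 0.95,
):
    """Slope, R^2 and index window of the initial linear segment.

    All contiguous windows of >= ``min_points`` points lying within the
    first ``early_fraction`` of the time span are evaluated; among those
    with R^2 >= ``r2_threshold`` the steepest (maximal ``|slope|``) wins.
    If none qualifies, the first ``min_points`` points are used.
    """
    t, y = trace.times, trace.a340
    if t[-1] == t[0]:
        raise ValueError("zero time span")
    limit = t[0] + early_fraction * (t[-1] - t[0])
    last = int(np.searchsorted(t, limit, side="right")) - 1
    best = None
    for i in range(0, last + 1):
        for j in range(i + min_points - 1, last + 1):
            slope, r2 = _linfit(t[i : j + 1], y[i : j + 1])
            if r2 >= r2_threshold:
                if best is None or abs(slope) > abs(best[0]):
                    best = (slope, r2, (i, j))
    if best is None:
        slope, r2 = _linfit(t[:min_points], y[:min_points])
        best = (slope, r2, (0, min_points - 1))
    return best


def slope_to_rate(slope: float, epsilon: float = EPSILON_NADPH, path_length: float = 1.0) -> float:
    """Convert an absorbance slope (AU/min) to mM/min (== umol/mL/min)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    return -slope / (epsilon * path_length) * 1000.0


def rate_for_trace(
    trace: AbsorbanceTrace,
    epsilon: float = EPSILON_NADPH,
    path_length: float = 1.0,
    **fit_kwargs,
) -> RateResult:
    """Fit one trace and convert its slope to a rate."""
    slope, r2, window = fit_initial_rate(trace, **fit_kwargs)
    return RateResult(
        enzyme=trace.enzyme,
        substrate=trace.substrate,
        cofactor=trace.cofactor,
        pH=trace.pH,
        slope=slope,
        rate=slope_to_rate(slope, epsilon, path_length),
        fit_window=window,
        r2=r2,
        path_length=path_length,
    )


def subtract_controls(tests: list, controls: list) -> list:
    """Net rates: per-condition test mean minus matched control mean.

    ``tests`` and ``controls`` are per-replicate :class:`RateResult`
    lists; replicates are averaged after fitting. Controls match on
    (substrate, cofactor, pH). A condition with no matched control raises,
    naming the condition. Negative nets are floored at 0 and flagged.
    """
    control_pool: dict = {}
    for c in controls:
        control_pool.setdefault((c.substrate, c.cofactor, c.pH), []).append(c.rate)

    grouped: dict = {}
    for t in tests:
        grouped.setdefault(t.condition, []).append(t)

    nets = []
    for condition in sorted(grouped, key=lambda k: (k[0], k[1], k[2], k[3])):
        members = grouped[condition]
        key = condition[1:]
        if key not in control_pool:
            raise ValueError(
                f"no matched control for condition (substrate={key[0]}, "
                f"cofactor={key[1]}, pH={key[2]})"
            )
        test_mean = float(np.mean([m.rate for m in members]))
        control_mean = float(np.mean(control_pool[key]))
        raw_net = test_mean - control_mean
        template = members[0]
        nets.append(
            replace(
                template,
                rate=test_mean,
                n_replicates=len(members),
                net_rate=max(0.0, raw_net),
                raw_net=raw_net,
                below_background=raw_net < 0,
            )
        )
    return nets


def build_heatmap(nets: list) -> pd.DataFrame:
    """Enzyme x (substrate, cofactor, pH) matrix of net rates.

    Missing conditions stay NaN (explicitly missing, never zero);
    duplicate condition keys raise.
    """
    seen = set()
    for n in nets:
        if n.condition in seen:
            raise ValueError(f"duplicate condition key {n.condition}")
        seen.add(n.condition)
    df = pd.DataFrame(
        {
            "enzyme": [n.enzyme for n in nets],
            "substrate": [n.substrate for n in nets],
            "cofactor": [n.cofactor for n in nets],
            "pH": [n.pH for n in nets],
            "net_rate": [n.net_rate for n in nets],
        }
    )
    matrix = df.pivot_table(
        index="enzyme",
        columns=["substrate", "cofactor", "pH"],
        values="net_rate",
        dropna=False,
    )
    return matrix.sort_index(axis=0).sort_index(axis=1)


def read_plate_csv(path: str | Path) -> list:
    """Read a long-format plate CSV into per-replicate traces."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return traces_from_frame(df)


def traces_from_frame(df: pd.DataFrame) -> list:
    """Group a long-format plate table into :class:`AbsorbanceTrace` objects."""
    traces = []
    keys = ["well", "enzyme", "substrate", "cofactor", "pH", "replicate"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            AbsorbanceTrace(
                well=str(key[0]),
                enzyme=str(key[1]),
                substrate=str(key[2]),
                cofactor=str(key[3]),
                pH=float(key[4]),
                replicate=int(key[5]),
                times=grp["time_min"].to_numpy(),
                a340=grp["a340"].to_numpy(),
            )
        )
    return traces


def plate_rates(
    df: pd.DataFrame,
    epsilon: float = EPSILON_NADPH,
    path_length: float = 1.0,
    control_enzymes=DEFAULT_CONTROL_ENZYMES,
):
    """End-to-end: long plate table -> net rates and heat-map matrix."""
    traces = traces_from_frame(df)
    results = [rate_for_trace(t, epsilon, path_length) for t in traces]
    tests = [r for r in results if r.enzyme not in control_enzymes]
    controls = [r for r in results if r.enzyme in control_enzymes]
    nets = subtract_controls(tests, controls)
    return nets, build_heatmap(nets)


def rates_to_frame(nets: list) -> pd.DataFrame:
    """Tabulate net rate results for TSV output."""
    return pd.DataFrame(
        {
            "enzyme": [n.enzyme for n in nets],
            "substrate": [n.substrate for n in nets],
            "cofactor": [n.cofactor for n in nets],
            "pH": [n.pH for n in nets],
            "rate": [n.rate for n in nets],
            "net_rate": [n.net_rate for n in nets],
            "raw_net": [n.raw_net for n in nets],
            "below_background": [n.below_background for n in nets],
            "n_replicates": [n.n_replicates for n in nets],
            "path_length": [n.path_length for n in nets],
        }
    )
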