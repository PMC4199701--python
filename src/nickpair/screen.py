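"""Screen count statistics: heritable mutation rates with exact intervals.

The heritable mutation rate of a guide (or guide pair) is the number of
mutant F1 progeny divided by all F1 progeny screened, reported as a
percentage.  Founder (G0) bookkeeping uses the same arithmetic: survival
= G0 adults / injected embryos, fertility = fertile G0 / G0 adults.

Intervals are exact Clopper-Pearson, chosen because observed rates
include zero and sub-1% values where normal-approximation intervals
misbehave.  Display rounding follows the reporting convention of the
screen tables: one decimal at >=1%, two decimals below 1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import D10A_WINDOW, H840A_WINDOW, GuidePair
from .locus import NickaseVariant
from .tables import CENSORED, ND, PairRow


@dataclass(frozen=True)
class ScreenRecord:
    """Counts for one screened unit (a single sgRNA or an sgRNA pair)."""

    unit: str
    variant: NickaseVariant
    n_f1_total: int
    n_f1_mutant: int
    offset: int | None = None
    # founder block
    n_embryos: int | None = None
    n_g0_adults: int | None = None
    n_g0_fertile: int | None = None
    n_hdr_yielding_g0: int | None = None
    # HDR marker block
    n_g1_total: int | None = None
    n_g1_positive: int | None = None

    def __post_init__(self) -> None:
        pairs = [
            ("n_f1_mutant", "n_f1_total", self.n_f1_mutant, self.n_f1_total),
            ("n_g0_adults", "n_embryos", self.n_g0_adults, self.n_embryos),
            ("n_g0_fertile", "n_g0_adults", self.n_g0_fertile, self.n_g0_adults),
            ("n_hdr_yielding_g0", "n_g0_fertile", self.n_hdr_yielding_g0, self.n_g0_fertile),
            ("n_g1_positive", "n_g1_total", self.n_g1_positive, self.n_g1_total),
        ]
        for num_name, den_name, num, den in pairs:
            if num is not None and num < 0:
                raise ValueError(f"{self.unit}: {num_name} negative")
            if num is not None and den is not None and num > den:
                raise ValueError(f"{self.unit}: {num_name} > {den_name}")


def clopper_pearson(k, n, confidence: float = 0.95):
    """Exact binomial CI as fractions; vectorized over k, n."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    alpha = 1.0 - confidence
    lo = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    hi = np.where(k < n, stats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


@dataclass(frozen=True)
class RateEstimate:
    """A percentage rate with its counts and 95% exact CI (percent)."""

    percent: float
    numerator: int
    denominator: int
    ci_low: float
    ci_high: float

    @property
    def display(self) -> float:
        """Rounded per reporting convention: 1 dp at >=1%, 2 dp below."""
        return round(self.percent, 1) if self.percent >= 1.0 else round(self.percent, 2)


def heritable_rate(n_mutant: int, n_total: int, confidence: float = 0.95) -> RateEstimate:
    """Mutant F1 over total F1 screened, as a percent with exact CI."""
    if n_total <= 0:
        raise ValueError("rate undefined: zero denominator")
    if not 0 <= n_mutant <= n_total:
        raise ValueError("numerator must lie in [0, denominator]")
    lo, hi = clopper_pearson(n_mutant, n_total, confidence)
    return RateEstimate(100.0 * n_mutant / n_total, n_mutant, n_total, 100 * lo, 100 * hi)


def g0_rates(rec: ScreenRecord) -> dict[str, RateEstimate]:
    """Founder-level rates: survival, fertility, HDR-yielding fraction."""
    if rec.n_embryos is None or rec.n_g0_adults is None:
        raise ValueError(f"{rec.unit}: founder block missing (embryos / G0 adults)")
    out = {"survival_pct": heritable_rate(rec.n_g0_adults, rec.n_embryos)}
    if rec.n_g0_fertile is not None:
        out["fertile_pct"] = heritable_rate(rec.n_g0_fertile, rec.n_g0_adults)
        if rec.n_hdr_yielding_g0 is not None:
            out["hdr_yielding_pct"] = heritable_rate(rec.n_hdr_yielding_g0, rec.n_g0_fertile)
    return out


def effective_window(variant: NickaseVariant) -> tuple[int, int]:
    if variant is NickaseVariant.D10A:
        return D10A_WINDOW
    if variant is NickaseVariant.H840A:
        return H840A_WINDOW
    raise ValueError("effective window is defined for nickase variants only")


@dataclass(frozen=True)
class PairSummary:
    table: pd.DataFrame
    mean_rate: float | None  # unweighted mean over in-window pairs (%)
    max_rate: float | None   # maximum in-window pair rate (%)
    n_effective: int


def summarize_pair_rates(
    rows: Iterable[PairRow],
    window: tuple[int, int],
) -> PairSummary:
    """Aggregate printed per-pair rates over an effective offset window.

    Censored ("<0.1%") and not-done cells are excluded from aggregates
    but kept in the table with their sentinel.  Scalars are computed on
    the rates at printed (one-decimal) precision.
    """
    recs = []
    for r in rows:
        measured = not isinstance(r.rate_pct, str)
        recs.append(
            {
                "offset": r.offset,
                "sgrna_a": r.sgrna_a,
                "sgrna_b": r.sgrna_b,
                "rate_pct": r.rate_pct if measured else np.nan,
                "flag": "" if measured else r.rate_pct,
                "in_window": window[0] <= r.offset <= window[1],
            }
        )
    table = pd.DataFrame(recs)
    if table.empty:
        return PairSummary(table, None, None, 0)
    eff = table[table.in_window & table.rate_pct.notna()]
    mean = round(float(eff.rate_pct.mean()), 1) if len(eff) else None
    mx = round(float(eff.rate_pct.max()), 1) if len(eff) else None
    return PairSummary(table, mean, mx, int(len(eff)))


def summarize_pairs(
    records: Iterable[ScreenRecord],
    geometry: dict[str, GuidePair],
    variant: NickaseVariant,
) -> PairSummary:
    """Join count records to pair geometry and aggregate heritable rates.

    Each record must join a :class:`GuidePair` by unit id; the emitted
    table carries offset, orientation, overhang and efficacy alongside
    the estimated rate.  Scalar aggregates (unweighted mean, max) run
    over display-rounded rates of pairs the classifier calls effective.
    """
    recs = []
    for rec in records:
        if rec.unit not in geometry:
            raise KeyError(f"screen record {rec.unit!r} has no matching guide pair")
        pair = geometry[rec.unit]
        rate = heritable_rate(rec.n_f1_mutant, rec.n_f1_total)
        oh = pair.overhang(variant)
        call = pair.efficacy(variant)
        recs.append(
            {
                "unit": rec.unit,
                "offset": pair.offset,
                "orientation": pair.orientation.value,
                "overhang_kind": oh.kind.value,
                "overhang_len": oh.length,
                "effective": call.effective,
                "reason": call.reason,
                "rate_pct": rate.display,
                "ci_low": rate.ci_low,
                "ci_high": rate.ci_high,
            }
        )
    table = pd.DataFrame(recs)
    if table.empty:
        return PairSummary(table, None, None, 0)
    eff = table[table.effective]
    mean = round(float(eff.rate_pct.mean()), 1) if len(eff) else None
    mx = round(float(eff.rate_pct.max()), 1) if len(eff) else None
    return PairSummary(table, mean, mx, int(len(eff)))


def compare_rates(a: RateEstimate, b: RateEstimate) -> float:
    """Two-sided Fisher exact p-value comparing two count-backed rates."""
    table = [
        [a.numerator, a.denominator - a.numerator],
        [b.numerator, b.denominator - b.numerator],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
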