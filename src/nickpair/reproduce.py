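"""End-to-end reproduction pipeline over the published white-locus screen.

Chains the synthetic fixtures through geometry and screen statistics and
checks the derived scalars against the published golden cells: the four
sequence-anchored pair offsets, the D10A effective-window mean and
maximum paired rates, the H840A maximum paired rate, and the two HDR
marker rates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import D10A_WINDOW, H840A_WINDOW, GuidePair, pair_offset
from .locus import NickaseVariant
from .screen import heritable_rate, g0_rates, summarize_pair_rates, ScreenRecord
from .synthetic import reconstruct_white_minilocus
from .tables import D10A_PAIR_ROWS, H840A_PAIR_ROWS, HDR_SCREEN

#: Published cells the pipeline must reproduce.
GOLDEN = {
    "offset_white-D_white-R": -15,
    "offset_white-D_white-H": -5,
    "offset_white-D_white-I": 6,
    "offset_white-D_white-C": 7,
    "d10a_mean_rate": 11.2,
    "d10a_max_rate": 21.2,
    "h840a_max_rate": 1.5,
    "hdr_rate_cas9": 30.5,
    "hdr_rate_d10a": 0.29,
}

_ALLOWED_KEYS = {
    "variant",
    "d10a_window",
    "h840a_window",
    "max_mm",
    "pair_span",
    "seed",
    "outdir",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    variant: str = "D10A"
    d10a_window: tuple[int, int] = D10A_WINDOW
    h840a_window: tuple[int, int] = H840A_WINDOW
    max_mm: int = 4
    pair_span: int = 200
    seed: int = 1234
    outdir: str = "nickpair_out"

    def __post_init__(self) -> None:
        NickaseVariant(self.variant)
        self.d10a_window = tuple(self.d10a_window)
        self.h840a_window = tuple(self.h840a_window)
        for w in (self.d10a_window, self.h840a_window):
            if len(w) != 2 or w[0] > w[1]:
                raise ValueError(f"bad window {w}")
        if self.max_mm < 0 or self.pair_span <= 0:
            raise ValueError("max_mm must be >= 0 and pair_span positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ReproductionReport:
    values: dict = field(default_factory=dict)
    mismatches: list = field(default_factory=list)
    log: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def run_reproduction(config: RunConfig | None = None, outdir: str | Path | None = None) -> ReproductionReport:
    """Run fixtures -> geometry -> screen summary -> HDR rates, check goldens.

    Every derived value is logged with its inputs; a golden mismatch is
    recorded (and makes ``report.ok`` false) rather than raised.
    """
    config = config or RunConfig()
    report = ReproductionReport()

    asm = reconstruct_white_minilocus()
    report.log.append(f"assembled {asm.locus.name}: {len(asm.locus)} nt, "
                      f"{len(asm.guides)} anchored guides")
    gd = asm.guides
    for other in ("white-R", "white-H", "white-I", "white-C"):
        off = pair_offset(gd["white-D"], gd[other])
        report.values[f"offset_white-D_{other}"] = off
        report.log.append(f"offset(white-D, {other}) = {off}")

    d10a = summarize_pair_rates(D10A_PAIR_ROWS, config.d10a_window)
    report.values["d10a_mean_rate"] = d10a.mean_rate
    report.values["d10a_max_rate"] = d10a.max_rate
    report.values["d10a_n_effective"] = d10a.n_effective
    report.log.append(
        f"D10A window {config.d10a_window}: n={d10a.n_effective}, "
        f"mean={d10a.mean_rate}, max={d10a.max_rate}"
    )
    h840a = summarize_pair_rates(H840A_PAIR_ROWS, config.h840a_window)
    report.values["h840a_max_rate"] = h840a.max_rate
    report.log.append(
        f"H840A window {config.h840a_window}: n={h840a.n_effective}, max={h840a.max_rate}"
    )

    for key, method in (("hdr_rate_cas9", "Cas9"), ("hdr_rate_d10a", "D10A")):
        c = HDR_SCREEN[method]
        rate = heritable_rate(c.n_g1_positive, c.n_g1_total)
        report.values[key] = rate.display
        rec = ScreenRecord(
            unit=method,
            variant=NickaseVariant.D10A if method == "D10A" else NickaseVariant.WT,
            n_f1_total=c.n_g1_total,
            n_f1_mutant=c.n_g1_positive,
            n_embryos=c.n_embryos,
            n_g0_adults=c.n_g0_adults,
            n_g0_fertile=c.n_g0_fertile,
            n_hdr_yielding_g0=c.n_hdr_yielding_g0,
        )
        founders = g0_rates(rec)
        for k, v in founders.items():
            report.values[f"{method.lower()}_{k}"] = v.display
        report.log.append(
            f"HDR {method}: {c.n_g1_positive}/{c.n_g1_total} -> {rate.display}%"
        )

    for key, expect in GOLDEN.items():
        got = report.values.get(key)
        if got != expect:
            report.mismatches.append(f"{key}: expected {expect}, got {got}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        d10a.table.to_csv(outdir / "d10a_pairs.tsv", sep="\t", index=False)
        h840a.table.to_csv(outdir / "h840a_pairs.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(
                {
                    "config": asdict(config),
                    "values": report.values,
                    "mismatches": report.mismatches,
                    "log": report.log,
                },
                fh,
                indent=2,
            )
    return report
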