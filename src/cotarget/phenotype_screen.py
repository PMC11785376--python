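"""Glass' effect-size screen for body-length phenotypes.

Candidate genes are knocked down or mutated and body length (microns) is
measured per animal.  Because measurements come from different genetic
backgrounds and experiments with different spreads, effects are normalized
as **Glass' delta**: the control-mean minus test-mean difference divided by
the *control* standard deviation, so larger delta means smaller animals and
the normalization does not borrow variance from the perturbed group.

``run_screen`` computes, per test group against the control group, Glass'
delta and a two-sided Welch two-sample p-value, applies Benjamini–Hochberg
adjustment across the screen, and flags hits at the joint cutoff
(adjusted p <= 0.05 AND delta >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PhenotypeGroup:
    """One genotype/treatment's body-length measurements (microns)."""

    label: str
    lengths: np.ndarray
    background: str = "wild-type"
    replicates: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        if arr.size < 2:
            raise ValueError(
                f"group {self.label!r}: need >= 2 measurements, got {arr.size}"
            )
        if (arr <= 0).any():
            raise ValueError(f"group {self.label!r}: lengths must be positive")
        object.__setattr__(self, "lengths", arr)

    @property
    def n(self) -> int:
        return int(self.lengths.size)


@dataclass(frozen=True)
class ScreenResult:
    label: str
    background: str
    delta: float
    pvalue: float
    adjusted_p: float
    hit: bool
    n: int


def glass_delta(control: PhenotypeGroup, test: PhenotypeGroup) -> float:
    """(mean(control) - mean(test)) / sd(control), sample sd (n-1).

    Signed so that larger delta means smaller test animals.  Raises
    ``ValueError`` when the control sd is zero.
    """
    sd = float(np.std(control.lengths, ddof=1))
    if sd == 0.0:
        raise ValueError("control group has zero standard deviation")
    return float((np.mean(control.lengths) - np.mean(test.lengths)) / sd)


def run_screen(
    groups: Sequence[PhenotypeGroup],
    control_label: str,
    p_cutoff: float = 0.05,
    delta_cutoff: float = 1.0,
) -> list[ScreenResult]:
    """Screen every non-control group against the control.

    Per group: Glass' delta and a two-sided Welch t-test p-value; adjusted
    p by Benjamini–Hochberg across all test groups; ``hit`` iff adjusted
    p <= ``p_cutoff`` AND delta >= ``delta_cutoff``.
    """
    by_label = {g.label: g for g in groups}
    if control_label not in by_label:
        raise ValueError(f"control group {control_label!r} missing")
    control = by_label[control_label]
    tests = [g for g in groups if g.label != control_label]
    if not tests:
        return []

    deltas, pvals = [], []
    for g in tests:
        deltas.append(glass_delta(control, g))
        pvals.append(
            float(stats.ttest_ind(control.lengths, g.lengths,
                                  equal_var=False).pvalue)
        )
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [
        ScreenResult(
            label=g.label,
            background=g.background,
            delta=d,
            pvalue=p,
            adjusted_p=float(q),
            hit=bool(q <= p_cutoff and d >= delta_cutoff),
            n=g.n,
        )
        for g, d, p, q in zip(tests, deltas, pvals, adj)
    ]


def read_phenotype_table(path: str | Path) -> list[PhenotypeGroup]:
    """Read a TSV with header condition, background, replicate, length_um
    into per-condition groups."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["condition", "background", "replicate", "length_um"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"expected header {required}, got {list(df.columns)}")
    groups = []
    for (cond, bg), sub in df.groupby(["condition", "background"], sort=True):
        groups.append(
            PhenotypeGroup(
                label=str(cond),
                lengths=sub["length_um"].to_numpy(float),
                background=str(bg),
                replicates=tuple(str(r) for r in sub["replicate"]),
            )
        )
    return groups


def write_screen_table(results: Sequence[ScreenResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "condition": [r.label for r in results],
            "background": [r.background for r in results],
            "n": [r.n for r in results],
            "glass_delta": [r.delta for r in results],
            "pvalue": [r.pvalue for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "hit": [r.hit for r in results],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
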