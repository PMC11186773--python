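"""Off-target editing validation from paired treated/control amplicon counts.

For every nominated site the editing frequency is the percentage of reads
carrying at least one source->target conversion (A->G for ABE) within
protospacer positions 4-10. Treated and control samples form a 2x2
contingency table (edited/unedited reads) tested with Pearson's chi-square
(1 df, no continuity correction by default), p-values are adjusted with
Benjamini-Hochberg across all sites of one comparison, and a site is
validated only when both criteria hold: FDR <= 0.05 and an editing-
frequency difference of at least 1 percentage point over control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import Alignment
from .errors import InvalidInputError, UncallableError
from .geometry import AmpliconRef, ProtospacerSpec

#: Protospacer positions scored for off-target conversions.
DEFAULT_SCORING_WINDOW = (4, 10)

#: CRISPRessoPooled-compatible settings used for the count path.
POOLED_BE_PRESET = {
    "quantification_window_size": 10,
    "quantification_window_center": -10,
    "base_editor_output": True,
    "conversion_nuc_from": "A",
    "conversion_nuc_to": "G",
}

REQUIRED_COLUMNS = ["site_id", "treated_edited", "treated_total", "control_edited", "control_total"]


@dataclass(frozen=True)
class SiteCounts:
    """Edited/total read counts for one site in treated and control samples."""

    site_id: str
    treated_edited: int
    treated_total: int
    control_edited: int
    control_total: int

    def __post_init__(self) -> None:
        for label, edited, total in (
            ("treated", self.treated_edited, self.treated_total),
            ("control", self.control_edited, self.control_total),
        ):
            if not 0 <= edited <= total:
                raise InvalidInputError(f"{label} counts invalid for site {self.site_id!r}")
            if total <= 0:
                raise UncallableError(f"{label} depth is zero for site {self.site_id!r}")


def classify_read_edited(
    aln: Alignment,
    amplicon: AmpliconRef,
    proto: ProtospacerSpec,
    window: tuple[int, int] = DEFAULT_SCORING_WINDOW,
    conversion: tuple[str, str] = ("A", "G"),
) -> bool:
    """Whether an aligned read carries a conversion in the scoring window.

    A read is edited iff at least one window position holds the source
    base in the reference (protospacer orientation) and the target base in
    the read. Reads gapped anywhere in the window do not cover it and
    raise :class:`UncallableError`; callers exclude them from numerator
    and denominator alike.
    """
    src, tgt = conversion
    cols = aln.columns_for_ref()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    edited = False
    for p in range(window[0], window[1] + 1):
        apos = proto.to_amplicon(p)
        if not 1 <= apos <= len(cols):
            raise UncallableError(f"protospacer position {p} outside aligned reference")
        col = cols[apos - 1]
        read_base = aln.read_aligned[col]
        if read_base == "-":
            raise UncallableError(f"read gapped at protospacer position {p}")
        ref_base = aln.ref_aligned[col]
        if proto.strand == "-":
            read_base, ref_base = comp[read_base], comp[ref_base]
        if ref_base == src and read_base == tgt:
            edited = True
    return edited


def editing_frequency(edited: int, total: int) -> float:
    """Editing frequency in percent: 100 * edited / total."""
    if total <= 0:
        raise UncallableError("editing frequency undefined at zero depth")
    if not 0 <= edited <= total:
        raise InvalidInputError(f"edited={edited} outside [0, total={total}]")
    return 100.0 * edited / total


def chisq_2x2(
    treated: tuple[int, int], control: tuple[int, int], yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 edited/unedited table, 1 df.

    ``treated`` and ``control`` are ``(edited, unedited)`` pairs. A table
    with a zero margin (e.g. no edited read in either sample) carries no
    signal and returns ``(0.0, 1.0)`` by convention. ``yates`` enables the
    continuity correction for sensitivity analysis.
    """
    a, b = treated
    c, d = control
    if min(a, b, c, d) < 0:
        raise InvalidInputError("counts must be non-negative")
    if a + b <= 0 or c + d <= 0:
        raise InvalidInputError("both samples need positive totals")
    if a + c == 0 or b + d == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=yates)
    return float(chi2), float(p)


def bh_fdr(pvalues: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_sites(
    counts: "pd.DataFrame | list[SiteCounts]",
    fdr_max: float = 0.05,
    delta_min: float = 1.0,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-site verdicts for one treated-vs-control comparison.

    Input columns: ``site_id, treated_edited, treated_total,
    control_edited, control_total``. Output adds ``f_treated, f_control``
    (percent), ``delta`` (percentage points, treated minus control),
    ``chi2, p, fdr`` and the dual-criterion ``validated`` flag. The FDR is
    adjusted across all sites of this comparison only.
    """
    if isinstance(counts, pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
        if missing:
            raise InvalidInputError(f"missing columns: {missing}")
        sites = [
            SiteCounts(
                site_id=str(r.site_id),
                treated_edited=int(r.treated_edited),
                treated_total=int(r.treated_total),
                control_edited=int(r.control_edited),
                control_total=int(r.control_total),
            )
            for r in counts.itertuples(index=False)
        ]
    else:
        sites = list(counts)
    if not sites:
        raise InvalidInputError("no sites to analyse")

    rows = []
    for s in sites:
        f_t = editing_frequency(s.treated_edited, s.treated_total)
        f_c = editing_frequency(s.control_edited, s.control_total)
        chi2, p = chisq_2x2(
            (s.treated_edited, s.treated_total - s.treated_edited),
            (s.control_edited, s.control_total - s.control_edited),
            yates=yates,
        )
        rows.append(
            {
                "site_id": s.site_id,
                "f_treated": f_t,
                "f_control": f_c,
                "delta": f_t - f_c,
                "chi2": chi2,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["validated"] = (out["fdr"] <= fdr_max) & (out["delta"] >= delta_min)
    return out


def read_site_counts(path: str) -> pd.DataFrame:
    """Read a site-counts CSV (columns as in :data:`REQUIRED_COLUMNS`)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    return df


def write_verdicts(verdicts: pd.DataFrame, path: str, fdr_max: float = 0.05, delta_min: float = 1.0) -> None:
    """Write per-site verdicts as CSV with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# shieldseq off-target verdicts; validated iff fdr<={fdr_max} and delta>={delta_min} pct points\n")
        verdicts.to_csv(path_or_buf=fh, index=False)
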