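"""Donor chimerism from polymorphic insertion-deletion marker reads.

Two genetically distinct human donors (e.g. a leukaemia xenograft donor
and an HSPC donor) are distinguished by a panel of polymorphic indel
markers. A marker is informative for a donor pair when one donor carries
an allele the other lacks; the fraction of cells derived from the target
donor is estimated as the unweighted mean, over informative markers, of
the proportion of donor-specific reads among total reads at that marker.
Host (mouse) reads are assumed to have been excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingGenotypeError, UncallableError

logger = logging.getLogger(__name__)

#: Marker totals below this depth trigger a warning (implausibly low for
#: a targeted chimerism panel; may indicate host contamination filtering
#: went wrong upstream).
LOW_DEPTH_WARNING = 50


def select_informative_markers(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Flag markers that discriminate a donor pair.

    ``genotypes`` columns: ``marker``, ``donor_a`` and ``donor_b`` (1 when
    the donor carries the marker allele, 0 when not; missing values are an
    error). Returns the frame with ``informative`` and ``informative_for``
    (``A``, ``B`` or empty) columns added. A marker is informative iff
    exactly one donor carries the allele.
    """
    for col in ("marker", "donor_a", "donor_b"):
        if col not in genotypes.columns:
            raise InvalidInputError(f"genotypes table missing column {col!r}")
    if genotypes[["donor_a", "donor_b"]].isna().any().any():
        missing = genotypes.loc[genotypes[["donor_a", "donor_b"]].isna().any(axis=1), "marker"]
        raise MissingGenotypeError(f"missing genotype for markers: {list(missing)}")
    out = genotypes.copy()
    a = out["donor_a"].astype(int)
    b = out["donor_b"].astype(int)
    if not set(a.unique()) <= {0, 1} or not set(b.unique()) <= {0, 1}:
        raise InvalidInputError("genotypes must be 0/1 allele presence flags")
    out["informative"] = a != b
    out["informative_for"] = np.where(~out["informative"], "", np.where(a > b, "A", "B"))
    return out


@dataclass
class ChimerismEstimate:
    """Donor fraction estimate with per-marker detail."""

    fraction: float
    per_marker: pd.DataFrame  # marker, donor_specific_reads, total_reads, proportion
    sd: float
    n_markers: int


def estimate_donor_fraction(counts: pd.DataFrame, weighted: bool = False) -> ChimerismEstimate:
    """Estimate the target-donor cell fraction from marker read counts.

    ``counts`` columns: ``marker``, ``donor_specific_reads``,
    ``total_reads``. The default estimator is the unweighted mean of
    per-marker proportions; ``weighted=True`` pools reads across markers
    (depth-weighted) instead. The sample standard deviation of per-marker
    proportions is reported as a dispersion diagnostic.
    """
    for col in ("marker", "donor_specific_reads", "total_reads"):
        if col not in counts.columns:
            raise InvalidInputError(f"counts table missing column {col!r}")
    usable = counts.loc[counts["total_reads"] > 0].copy()
    if usable.empty:
        raise UncallableError("no informative marker has reads")
    if (usable["donor_specific_reads"] > usable["total_reads"]).any():
        raise InvalidInputError("donor-specific reads exceed total reads")
    if (usable["total_reads"] < LOW_DEPTH_WARNING).any():
        low = usable.loc[usable["total_reads"] < LOW_DEPTH_WARNING, "marker"]
        logger.warning("implausibly low depth at markers %s", list(low))

    usable["proportion"] = usable["donor_specific_reads"] / usable["total_reads"]
    if weighted:
        fraction = float(usable["donor_specific_reads"].sum() / usable["total_reads"].sum())
    else:
        fraction = float(usable["proportion"].mean())
    sd = float(usable["proportion"].std(ddof=1)) if len(usable) > 1 else 0.0
    return ChimerismEstimate(
        fraction=fraction,
        per_marker=usable[["marker", "donor_specific_reads", "total_reads", "proportion"]].reset_index(drop=True),
        sd=sd,
        n_markers=int(len(usable)),
    )
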