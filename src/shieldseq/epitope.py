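"""Epitope-residue calling from an alanine-scan binding matrix.

Each alanine variant is screened against a panel of antibodies and scored
as residual binding in percent of the wild-type signal. A residue is a
candidate epitope residue for antibody *m* when its alanine variant
retains at most ``lo`` (default 20%) binding for *m* while keeping more
than ``hi`` (default 70%) for at least one other antibody - the other
antibodies act as folding/expression controls. Variants that lose binding
to every antibody are excluded as likely global (structural or
expression) effects rather than epitope hits. Downstream prioritisation
removes cysteines (disulfide bridges), residues with post-translational
modifications or domain-interface roles, and flags buried residues as
likely indirect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InsufficientControlsError, InvalidInputError, MissingAnnotationError


@dataclass
class EpitopeCalls:
    """Per-antibody candidate residues plus globally excluded residues."""

    candidates: dict[str, list[str]]
    excluded: list[str]
    lo: float
    hi: float

    def all_candidates(self) -> list[str]:
        seen: dict[str, None] = {}
        for residues in self.candidates.values():
            for r in residues:
                seen[r] = None
        return list(seen)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 2:
        raise InsufficientControlsError(
            "epitope calling needs >= 2 antibodies so that non-target antibodies can serve as controls"
        )
    if matrix.index.duplicated().any():
        raise InvalidInputError("duplicate residue identifiers in binding matrix")
    if (matrix.to_numpy() < 0).any():
        raise InvalidInputError("residual binding values must be >= 0")


def call_epitope_residues(
    matrix: pd.DataFrame,
    lo: float = 20.0,
    hi: float = 70.0,
    strict: bool = False,
) -> EpitopeCalls:
    """Call candidate epitope residues from a variants x antibodies matrix.

    ``matrix``: index = residue labels (e.g. ``K352``), columns = antibody
    names, values = residual binding in percent of wild type. With the
    default inclusive reading a candidate satisfies ``binding <= lo`` for
    one antibody and ``binding > hi`` for at least one other; ``strict``
    switches the low side to ``< lo``. Residues low for *all* antibodies
    are excluded as global-loss variants.
    """
    _check_matrix(matrix)
    low = (matrix < lo) if strict else (matrix <= lo)
    high = matrix > hi

    excluded = list(matrix.index[low.all(axis=1)])
    candidates: dict[str, list[str]] = {m: [] for m in matrix.columns}
    for residue in matrix.index:
        if residue in excluded:
            continue
        for m in matrix.columns:
            if low.at[residue, m] and high.loc[residue].drop(m).any():
                candidates[m].append(residue)
    return EpitopeCalls(candidates=candidates, excluded=excluded, lo=lo, hi=hi)


REASON_CYSTEINE = "cysteine"
REASON_PTM_INTERFACE = "ptm_or_interface"
REASON_BURIED = "buried_likely_indirect"
REASON_RETAINED = "retained"


def prioritize_residues(
    candidates: list[str],
    annotations: pd.DataFrame,
    buried_max: float = 10.0,
) -> pd.DataFrame:
    """Filter and flag candidate residues using structural annotations.

    ``annotations``: index = residue labels, columns ``wt_aa``,
    ``surface_accessibility`` (percent), ``is_cysteine``,
    ``ptm_or_interface``. Cysteines and PTM/interface residues are
    removed; residues with accessibility below ``buried_max`` are kept but
    flagged as likely indirect (a buried residue cannot contact an
    antibody directly, so its binding loss is presumed structural).
    Returns a frame with ``residue, status, reason``.
    """
    rows = []
    for residue in candidates:
        if residue not in annotations.index:
            raise MissingAnnotationError(f"no annotation for candidate residue {residue!r}")
        ann = annotations.loc[residue]
        acc = float(ann["surface_accessibility"])
        if not 0 <= acc <= 100:
            raise InvalidInputError(f"accessibility {acc} outside [0, 100] for {residue!r}")
        if bool(ann.get("is_cysteine", False)):
            rows.append({"residue": residue, "status": "removed", "reason": REASON_CYSTEINE})
        elif bool(ann.get("ptm_or_interface", False)):
            rows.append({"residue": residue, "status": "removed", "reason": REASON_PTM_INTERFACE})
        elif acc < buried_max:
            rows.append({"residue": residue, "status": "flagged", "reason": REASON_BURIED})
        else:
            rows.append({"residue": residue, "status": "retained", "reason": REASON_RETAINED})
    return pd.DataFrame(rows, columns=["residue", "status", "reason"])


def read_binding_matrix(path: str) -> pd.DataFrame:
    """Read a binding matrix CSV: residue, wt_aa, then one column per mAb."""
    df = pd.read_csv(path, comment="#")
    if "residue" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'residue' column")
    df = df.set_index("residue")
    return df.drop(columns=[c for c in ("wt_aa",) if c in df.columns])


def read_annotations(path: str) -> pd.DataFrame:
    """Read a residue-annotation CSV indexed by residue label."""
    df = pd.read_csv(path, comment="#")
    if "residue" not in df.columns:
        raise InvalidInputError(f"{path}: missing 'residue' column")
    return df.set_index("residue")
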