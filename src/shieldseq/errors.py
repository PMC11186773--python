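"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ShieldSeqError`, so callers can
catch pipeline failures without masking programming errors.
"""


class ShieldSeqError(Exception):
    """Base class for all pipeline errors."""


class InvalidSequenceError(ShieldSeqError):
    """A sequence violates its alphabet or length constraints."""


class GuideNotFoundError(ShieldSeqError):
    """The guide sequence matches the amplicon on neither strand."""


class AmbiguousGuideError(ShieldSeqError):
    """The guide sequence matches the amplicon at more than one locus."""


class OutOfBoundsError(ShieldSeqError):
    """A resolved window falls outside the amplicon."""


class FrameError(ShieldSeqError):
    """The CDS anchor is inconsistent with the amplicon sequence."""


class EmptyInputError(ShieldSeqError):
    """An operation received no usable input (e.g. zero reads)."""


class UntranslatableAlleleError(ShieldSeqError):
    """A window allele cannot be translated (contains N)."""


class TooManyOutcomesError(ShieldSeqError):
    """Edit-outcome enumeration would exceed the combinatorial cap."""


class UncallableError(ShieldSeqError):
    """A read or site cannot be scored (window not covered, zero depth)."""


class InvalidInputError(ShieldSeqError):
    """A numeric input violates its documented domain."""


class InsufficientControlsError(ShieldSeqError):
    """Epitope calling needs at least two antibodies as mutual controls."""


class MissingAnnotationError(ShieldSeqError):
    """A candidate residue has no annotation row."""


class MissingGenotypeError(ShieldSeqError):
    """A marker lacks a genotype for one of the donors."""


class InvalidSpecError(ShieldSeqError):
    """A simulation spec violates its invariants."""
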