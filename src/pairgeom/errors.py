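"""Exception hierarchy for the pairgeom pipeline.

Every stage raises a subclass of :class:`PairgeomError` so the CLI can surface
the failing stage with a nonzero exit code.
"""


class PairgeomError(Exception):
    """Base class for all package errors."""


class MsaParseError(PairgeomError):
    """Input alignment file could not be parsed at all."""


class MalformedAlignmentError(MsaParseError):
    """A row's aligned length disagrees with the query's column count."""


class AlphabetError(MsaParseError):
    """A sequence contains a symbol outside the residue+gap alphabet."""


class CapabilityError(PairgeomError):
    """An optional feature was requested but its dependency is unavailable."""


class CapacityError(PairgeomError):
    """Input exceeds an embedder's positional limit."""


class ShapeError(PairgeomError):
    """Tensor dimensions disagree with the pipeline contract."""


class StructureParseError(PairgeomError):
    """Backbone coordinate file could not be read."""


class InsufficientStructureError(StructureParseError):
    """Fewer than two complete residues after filtering."""


class DegenerateGeometryError(PairgeomError):
    """Collinear or coincident atoms where a frame is required."""


class UndefinedMetricError(PairgeomError):
    """A metric has no defined value on this instance (e.g. no eligible pairs)."""


class SchemaError(PairgeomError):
    """Restraint/checkpoint container is missing a key or has a bad version."""


class RestraintValidationError(PairgeomError):
    """Restraint arrays fail the posterior-normalization check."""
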