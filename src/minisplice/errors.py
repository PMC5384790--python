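"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`MinispliceError`, so callers can catch one type at a pipeline
boundary while still distinguishing coordinate problems from, say,
peak-assignment ambiguity.
"""


class MinispliceError(Exception):
    """Base class for all errors raised by minisplice."""


class CoordinateError(MinispliceError):
    """A coding-DNA (c.) position or interval does not fit the construct."""


class StructureError(MinispliceError):
    """Segment ordering violates the reporter-construct grammar."""


class DesignError(MinispliceError):
    """A microdeletion request cannot honor the protected exon ends."""


class SpanError(MinispliceError):
    """An edit or event span exceeds the segment it applies to."""


class CompositionError(MinispliceError):
    """Two splicing events on one exon side cannot be combined."""


class UnsupportedDescriptionError(MinispliceError):
    """The event set has no representation in the supported HGVS r. grammar."""


class CatalogError(MinispliceError):
    """A candidate-transcript catalog is malformed (e.g. duplicate labels)."""


class NoAmplificationError(MinispliceError):
    """A primer binding site is absent from the transcript."""


class AmbiguityError(MinispliceError):
    """Peak-assignment tolerance would allow one peak to match two candidates."""


class QuantificationError(MinispliceError):
    """Peak areas cannot be turned into fractions (e.g. zero total area)."""


class ContextError(MinispliceError):
    """A sequence-dependent operation lacks the sequence it needs."""


class AnnotationError(MinispliceError):
    """A transcript or variant is missing annotation required downstream."""


class ConfigurationError(MinispliceError):
    """An assay bundle or catalog is inconsistent (e.g. no canonical label)."""


class AlphabetError(MinispliceError):
    """A sequence contains characters outside A/C/G/T."""


class SpecError(MinispliceError):
    """A synthetic-data specification is internally impossible."""
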