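"""Exception hierarchy shared across fampri modules."""


class FampriError(Exception):
    """Base class for all fampri errors."""


class PedigreeStructureError(FampriError):
    """A pedigree violates a structural invariant (missing parent, duplicate id, ...)."""


class PedigreeCycleError(PedigreeStructureError):
    """An individual is its own ancestor; the offending path is in the message."""


class PedigreeLoopError(FampriError):
    """The pedigree contains a marriage/inbreeding loop, which peeling does not support."""


class DiseaseModelError(FampriError):
    """Inconsistent disease-model parameters (no allele frequency solves the prevalence, ...)."""


class ConfigurationError(FampriError):
    """A run configuration references unknown samples or fails schema validation."""


class DataError(FampriError):
    """A data file is malformed at a specific record."""
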