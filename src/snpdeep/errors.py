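"""Exception hierarchy shared across the package."""


class SnpDeepError(Exception):
    """Base class for all package errors."""


class ValidationError(SnpDeepError, ValueError):
    """A configuration or argument violates its documented contract."""


class FormatError(SnpDeepError, ValueError):
    """An input file violates the expected CSV dialect."""


class MergeError(SnpDeepError, ValueError):
    """Genotype and phenotype tables cannot be merged."""


class EmptyDatasetError(SnpDeepError, ValueError):
    """A filtering step removed every SNP or sample."""


class TrainingError(SnpDeepError, RuntimeError):
    """Model training failed (non-finite loss, bad architecture, ...)."""
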