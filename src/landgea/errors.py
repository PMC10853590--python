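"""Exception hierarchy shared across the pipeline stages."""


class LandgeaError(Exception):
    """Base class for all errors raised by landgea."""


class ConfigurationError(LandgeaError):
    """A parameter or configuration value is outside its documented domain."""


class FormatError(LandgeaError):
    """An input file violates its format contract (VCF/CSV/BED/GFF)."""


class UnsupportedInputError(LandgeaError):
    """Input is well-formed but outside scope (e.g. non-diploid genotypes)."""


class PreconditionError(LandgeaError):
    """An operation's stated precondition does not hold (e.g. unsorted loci)."""


class DegenerateDataError(LandgeaError):
    """Data degenerate for the requested statistic (constant column, all-missing locus)."""


class CollinearityError(LandgeaError):
    """Predictor table is rank deficient; message names the collinear columns."""


class NoSignalError(LandgeaError):
    """A model found nothing to fit (all loci at R² <= 0, empty candidate set)."""
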