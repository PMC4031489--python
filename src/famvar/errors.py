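"""Exception hierarchy shared across the package."""


class FamvarError(Exception):
    """Base class for all package-specific errors."""


class InvalidVariantError(FamvarError):
    """Variant key violates a structural rule (e.g. ref == alt)."""


class InvalidAlleleError(InvalidVariantError):
    """Allele string contains characters outside A/C/G/T."""


class PedigreeError(FamvarError):
    """Pedigree is malformed: dangling parent link, cycle, or bad relation."""


class FormatError(FamvarError):
    """Input file does not conform to its declared format."""


class DuplicateKeyError(FormatError):
    """Two rows map to the same variant key."""


class RangeError(FormatError):
    """A numeric field is outside its legal domain."""


class MissingAnnotationError(FamvarError):
    """A callset variant has no annotation row under strict mode."""


class ConfigError(FamvarError):
    """Configuration value is inconsistent or unknown."""


class NotApplicableError(FamvarError):
    """Operation is undefined for this input (e.g. Ti/Tv of an indel)."""


class InputError(FamvarError):
    """Two inputs that must describe the same universe do not."""
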