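"""Exception hierarchy for the bsamap pipeline."""


class BsamapError(Exception):
    """Base class for expected, user-facing pipeline errors."""


class ConfigError(BsamapError):
    """Invalid configuration: bad parameters, missing samples, etc."""


class FormatError(BsamapError):
    """A file does not conform to the expected format."""


class FineMapError(BsamapError):
    """Fine-mapping cannot proceed (e.g. no marker flanks the locus)."""


class AnnotationError(BsamapError):
    """Variant-effect annotation failure (e.g. REF/genome mismatch)."""
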