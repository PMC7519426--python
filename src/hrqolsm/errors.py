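"""Exception hierarchy; everything user-facing derives from HrqolsmError."""


class HrqolsmError(ValueError):
    """Base class for validation failures in the pipeline."""


class TaxonomyError(HrqolsmError):
    """Malformed taxonomy / concept-map fixture."""


class CorpusError(HrqolsmError):
    """Malformed corpus file or invalid corpus operation."""


class GeneratorError(HrqolsmError):
    """Invalid synthetic-corpus configuration or missing lexicon material."""


class LexiconError(HrqolsmError):
    """Malformed keyword or trigger-phrase lexicon."""


class AnnotationError(HrqolsmError):
    """Annotation aggregation failure (e.g. unmapped alias)."""


class CoverageError(HrqolsmError):
    """Coverage rate undefined or inconsistent inputs."""
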