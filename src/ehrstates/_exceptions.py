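"""Exception types shared across the pipeline."""


class CohortSpecError(ValueError):
    """A synthetic cohort specification failed validation.

    The message always names the offending field.
    """


class SchemaError(ValueError):
    """An input table is missing required columns or has unusable values."""


class EmptyCohortError(ValueError):
    """Every patient or snapshot was filtered out; nothing left to analyse."""
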