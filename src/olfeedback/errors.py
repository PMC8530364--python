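"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A configuration or parameter value violates a model invariant.

    The message always names the violated constraint.
    """


class UndefinedSimilarityError(ValueError):
    """Cosine similarity requested for a zero vector or empty odor set."""


class DegenerateRegimeError(ValueError):
    """A feedback-shifted cortical count collapsed to zero or below.

    The analytic expressions assume the shifted counts stay positive; when a
    count collapses the linear law no longer applies and we raise instead of
    clamping.
    """


class RegimeError(ValueError):
    """A closed-form expression was requested outside its regime of validity."""
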