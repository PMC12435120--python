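"""Exception hierarchy for screenbounds."""


class ScreenBoundsError(Exception):
    """Base class for all package errors."""


class ParameterError(ScreenBoundsError, ValueError):
    """An input value violates a domain-type invariant.

    The message always names the offending field.
    """


class ConsistencyError(ScreenBoundsError, ValueError):
    """Two inputs that must agree (e.g. on prevalence) do not."""


class FeasibilityError(ScreenBoundsError, ValueError):
    """A requested quantity lies outside its feasible range."""
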