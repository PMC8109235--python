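"""Exception and warning types shared across the package."""


class InvalidModelError(ValueError):
    """A slab stack or structure violates a model invariant."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (contrasts, components, fits)."""


class ParseError(ValueError):
    """A data file does not match the expected ASCII dialect."""


class CoverageWarning(UserWarning):
    """A fine grid does not span the full resolution kernel support."""


class ConvergenceWarning(UserWarning):
    """An optimiser or sampler finished without meeting its tolerance."""
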