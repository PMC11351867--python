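"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A spec/config object violates its invariants; message names the field."""


class LoadError(IOError):
    """A volume could not be loaded or does not match the reference grid."""


class ExternalDependencyMissing(RuntimeError):
    """An optional external backend (weights or library) is unavailable."""


class InteractionRequiredError(RuntimeError):
    """A slice was routed to manual interaction but no box provider exists."""
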