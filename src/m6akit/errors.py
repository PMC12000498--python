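"""Exception hierarchy for the pipeline.

All user-facing failures derive from :class:`M6AKitError` so the CLI can
catch one type and exit non-zero with a clean message.
"""


class M6AKitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(M6AKitError):
    """Malformed on-disk input (bad column, duplicate id, negative count...)."""


class StructureError(M6AKitError):
    """Structurally invalid object (cyclic tree, two roots, missing node)."""


class ParameterError(M6AKitError):
    """Out-of-range or inconsistent parameter value."""


class ConfigError(M6AKitError):
    """Invalid pipeline configuration."""


class NormalizationError(M6AKitError):
    """Size-factor computation impossible (e.g. no gene expressed everywhere)."""


class DegenerateInputError(M6AKitError):
    """Input degenerate for the requested statistic (e.g. constant vector)."""
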