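"""Exception hierarchy shared across the package."""


class KinvarError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KinvarError):
    """A resource file is syntactically malformed (names the offending line)."""


class ValidationError(KinvarError):
    """A parsed value violates a documented domain constraint."""


class StructuralError(KinvarError):
    """The ontology graph violates a structural invariant (cycle, dangling parent)."""


class ConfigurationError(KinvarError):
    """A run configuration is internally inconsistent."""


class ContractError(KinvarError):
    """An inter-module call contract was violated (e.g. feature-column mismatch)."""
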