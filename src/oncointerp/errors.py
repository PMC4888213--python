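"""Exception hierarchy shared across the package."""


class OncoInterpError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OncoInterpError, ValueError):
    """Input violates a domain precondition (bad base, negative mass, ...)."""


class ConfigurationError(OncoInterpError, ValueError):
    """Invalid runtime configuration (unknown sample label, bad class name)."""


class VCFParseError(OncoInterpError, ValueError):
    """A VCF could not be parsed; message names the offending file/line."""


class KnowledgeBaseError(OncoInterpError, ValueError):
    """A knowledge-base table is missing or malformed."""


class PredicateError(KnowledgeBaseError):
    """A biomarker predicate string could not be parsed."""


class AssemblyError(OncoInterpError, ValueError):
    """A findings document section could not be assembled."""
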