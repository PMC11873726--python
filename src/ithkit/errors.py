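"""Exception hierarchy used across the toolkit."""


class IthkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(IthkitError):
    """Malformed input file (duplicate ids, bad structure, ...)."""


class ParseError(FormatError):
    """Unparseable cell/token; message carries the location."""


class ConfigError(IthkitError):
    """Invalid configuration value."""


class TreeStructureError(IthkitError):
    """Clone tree is not a single-rooted connected acyclic graph."""


class LookupError_(IthkitError):
    """Unknown clone/gene/sample identifier."""


class UndefinedStatisticError(IthkitError):
    """Statistic is mathematically undefined on the given input
    (constant vector correlation, zero-norm cosine, empty repertoire...)."""


class ArgumentError(IthkitError):
    """Invalid argument to an operation."""
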