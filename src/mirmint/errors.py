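"""Exception hierarchy.

All package errors derive from :class:`MirmintError` so callers can catch
one type; the subclasses distinguish bad configuration, malformed files
and matrix/design mismatches.
"""


class MirmintError(Exception):
    """Base class for all mirmint errors."""


class ConfigError(MirmintError, ValueError):
    """A configuration value is missing, out of range or inconsistent."""


class FormatError(MirmintError, ValueError):
    """An input file violates its format contract."""


class DesignError(MirmintError, ValueError):
    """Expression matrix and design (sample→group map) disagree."""
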