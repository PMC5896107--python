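"""Exception hierarchy shared by every reader, writer and pipeline stage.

Readers distinguish *record-level* problems (collected into a
:class:`~miexchange.model.ParseReport`, parsing continues) from *fatal*
problems (a dialect we do not speak, a reference that cannot resolve),
which raise one of the exceptions below.
"""


class MiExchangeError(Exception):
    """Base class for all errors raised by this library."""


class UnsupportedDialectError(MiExchangeError):
    """A format/version the registry does not support (e.g. a 17-column MITAB row)."""


class CapabilityError(MiExchangeError):
    """A direction the support matrix forbids (e.g. reading MI-JSON) or a
    construct the requested version cannot express (e.g. a complex at XML 2.5)."""


class MalformedFieldError(MiExchangeError):
    """A single cell that does not parse (unbalanced quotes/parentheses)."""

    def __init__(self, message: str, column: int | None = None, line: int | None = None):
        super().__init__(message)
        self.column = column
        self.line = line


class DanglingReferenceError(MiExchangeError):
    """A numeric reference in a compact XML document with no definition in its entry."""

    def __init__(self, ref_id: int, kind: str = "object"):
        super().__init__(f"dangling {kind} reference: id {ref_id} is not defined in this entry")
        self.ref_id = ref_id
        self.kind = kind


class AmbiguousHubError(MiExchangeError):
    """Spoke expansion asked for a unique bait and found zero or several."""


class ConfigurationError(MiExchangeError):
    """A fetcher backing file, rule table or ontology that cannot be used as configured."""
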