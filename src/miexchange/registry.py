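"""Format registry: the single place that knows which (format, version,
direction) triples this library supports, and hands out the matching
reader or writer.

The accepted pairs are exactly the support matrix: MITAB 2.5/2.6/2.7 and
PSI-MI XML 2.5/3.0 in both directions, MI-JSON and HTML write-only.
"""

from __future__ import annotations

from typing import Callable, Optional

from . import htmlout, mijson, mitab, xmlio
from .errors import CapabilityError, UnsupportedDialectError
from .model import FormatDescriptor

#: Short dialect names used by the CLI, mapped to (format, version).
DIALECTS = {
    "mitab25": ("mitab", "2.5"),
    "mitab26": ("mitab", "2.6"),
    "mitab27": ("mitab", "2.7"),
    "xml25": ("psi-xml", "2.5"),
    "xml30": ("psi-xml", "3.0"),
    "mijson": ("mi-json", None),
    "html": ("html", None),
}

_SUPPORTED: set[tuple[str, Optional[str], str]] = {
    ("mitab", "2.5", "read"), ("mitab", "2.5", "write"),
    ("mitab", "2.6", "read"), ("mitab", "2.6", "write"),
    ("mitab", "2.7", "read"), ("mitab", "2.7", "write"),
    ("psi-xml", "2.5", "read"), ("psi-xml", "2.5", "write"),
    ("psi-xml", "3.0", "read"), ("psi-xml", "3.0", "write"),
    ("mi-json", None, "write"),
    ("html", None, "write"),
}


def supported_descriptors() -> list[FormatDescriptor]:
    """Every descriptor the registry accepts, deterministically ordered."""
    return [
        FormatDescriptor(format=f, version=v, direction=d)
        for f, v, d in sorted(_SUPPORTED, key=lambda t: (t[0], t[1] or "", t[2]))
    ]


def is_supported(descriptor: FormatDescriptor) -> bool:
    return (descriptor.format, descriptor.version, descriptor.direction) in _SUPPORTED


def lookup(descriptor: FormatDescriptor) -> Callable:
    """Return the reader/writer for a descriptor, or raise.

    Write-only formats in the read direction raise :class:`CapabilityError`
    (they can never be read); an unknown format/version combination raises
    :class:`UnsupportedDialectError`.
    """
    fmt, version, direction = descriptor.format, descriptor.version, descriptor.direction
    if fmt in ("mi-json", "html") and direction == "read":
        # FormatDescriptor construction already rejects this, but callers may
        # probe with raw triples through `probe`
        raise CapabilityError(f"{fmt} is write-only")
    if not is_supported(descriptor):
        raise UnsupportedDialectError(
            f"no support for format={fmt!r} version={version!r} direction={direction!r}"
        )
    table: dict[tuple[str, str], Callable] = {
        ("mitab", "read"): mitab.read_mitab,
        ("mitab", "write"): mitab.write_mitab,
        ("psi-xml", "read"): xmlio.read_xml,
        ("psi-xml", "write"): xmlio.write_xml,
        ("mi-json", "write"): mijson.write_mijson,
        ("html", "write"): htmlout.write_html,
    }
    return table[(fmt, direction)]


def probe(fmt: str, direction: str, version: Optional[str] = None) -> FormatDescriptor:
    """Build + validate a descriptor from raw strings.

    Raises :class:`CapabilityError` for a write-only format in the read
    direction and :class:`UnsupportedDialectError` for anything else the
    matrix does not contain.
    """
    if fmt in ("mi-json", "html") and direction == "read":
        raise CapabilityError(f"{fmt} is write-only: reading is not supported")
    try:
        descriptor = FormatDescriptor(format=fmt, version=version, direction=direction)
    except ValueError as exc:
        raise UnsupportedDialectError(str(exc)) from exc
    if not is_supported(descriptor):
        raise UnsupportedDialectError(
            f"no support for format={fmt!r} version={version!r} direction={direction!r}"
        )
    return descriptor
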