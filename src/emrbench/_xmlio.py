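"""Shared XML plumbing: schema-validated parsing and canonical serialization.

Every interchange document is UTF-8 and is emitted by a deterministic writer
(fixed element/attribute order, two-space indentation), so writing the same
in-memory object twice always yields byte-identical output and round-trips
are exact.
"""
from __future__ import annotations

import io
import os
from importlib import resources

from lxml import etree

from .errors import ParseError, SchemaValidationError

_SCHEMA_CACHE: dict[str, etree.RelaxNG] = {}


def _schema(name: str) -> etree.RelaxNG:
    if name not in _SCHEMA_CACHE:
        ref = resources.files("emrbench.schemas").joinpath(name)
        with ref.open("rb") as fh:
            _SCHEMA_CACHE[name] = etree.RelaxNG(etree.parse(fh))
    return _SCHEMA_CACHE[name]


def parse_validated(source, schema_name: str) -> etree._Element:
    """Parse ``source`` (path or binary file-like) and validate it against the
    shipped RELAX NG schema, returning the root element.

    Raises ParseError for malformed XML (message carries the line number) and
    SchemaValidationError naming the offending element otherwise.
    """
    if isinstance(source, (str, os.PathLike)):
        src = os.fspath(source)
    else:
        src = source
    try:
        tree = etree.parse(src)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    rng = _schema(schema_name)
    if not rng.validate(tree):
        err = rng.error_log.last_error
        detail = f"{err.message} (line {err.line})" if err is not None else "unknown"
        raise SchemaValidationError(
            f"document does not conform to {schema_name}: {detail}"
        )
    return tree.getroot()


def _indent(el: etree._Element, level: int = 0) -> None:
    # Structural elements (text is None) get indentation; elements carrying
    # text content — even whitespace-only — are left untouched so content
    # round-trips exactly.
    children = list(el)
    if not children:
        return
    pad = "\n" + "  " * (level + 1)
    if el.text is None:
        el.text = pad
    for i, child in enumerate(children):
        _indent(child, level + 1)
        child.tail = pad if i < len(children) - 1 else "\n" + "  " * level


def serialize(root: etree._Element) -> bytes:
    """Canonical bytes for an element tree built in writer order."""
    _indent(root)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8") + b"\n"


def write_document(root: etree._Element, sink) -> None:
    """Write canonical bytes to ``sink`` (path or binary file-like)."""
    data = serialize(root)
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wb") as fh:
            fh.write(data)
    else:
        sink.write(data)


def as_source(data: bytes) -> io.BytesIO:
    """Convenience wrapper turning raw bytes into a parse source."""
    return io.BytesIO(data)
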