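"""Reading, writing and exporting set data.

The *sets file* is a FASTA-like plain-text format::

    #vennkit sets v1
    >First set name
    element1
    element2
    >Second set name
    ...

One ``>``-headed block per set (1..6 blocks, distinct names), one
element per line.  Only a line-initial ``>`` is structural; a ``>``
elsewhere in an element is plain text.  An element that itself starts
with ``>`` is written with one leading space, which normalization
strips again on read, so write→read round-trips every family exactly
and write∘read∘write is byte-identical.

All writers are atomic: output goes to a temporary sibling file that is
renamed into place only on success, so a failed run leaves no partial
file behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Union

from .errors import FormatError, ValidationError
from .setcore import MAX_SETS, RegionTable, SetFamily, build_family
from .unions import QuotientRegionTable

__all__ = [
    "VERSION_LINE",
    "write_sets_file",
    "read_sets_file",
    "export_region_elements",
    "export_counts",
]

VERSION_LINE = "#vennkit sets v1"

PathLike = Union[str, Path]


def _atomic_write_text(destination: PathLike, text: str) -> None:
    destination = Path(destination)
    fd, tmp = tempfile.mkstemp(
        dir=destination.parent or Path("."), prefix=f".{destination.name}.", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, destination)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def format_sets_file(family: SetFamily) -> str:
    """The deterministic byte content of a family's sets file."""
    lines = [VERSION_LINE]
    for s in family.sets:
        lines.append(f">{s.name}")
        for el in s.elements:
            # a leading space shields a line-initial '>' and is stripped on read
            lines.append(f" {el}" if el.startswith(">") else el)
    return "\n".join(lines) + "\n"


def write_sets_file(family: SetFamily, destination: PathLike) -> None:
    """Write the family to ``destination`` in the sets-file format."""
    _atomic_write_text(destination, format_sets_file(family))


def parse_sets_file(text: str) -> SetFamily:
    """Parse sets-file text into a family (see :func:`read_sets_file`)."""
    lines = text.splitlines()
    if not lines or lines[0].strip() != VERSION_LINE:
        raise FormatError(f"missing version line {VERSION_LINE!r}", line=1)
    entries: list[tuple[str, list[str]]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith(">"):
            name = line[1:].strip()
            if not name:
                raise FormatError("empty set name", line=lineno)
            if any(name == existing for existing, _ in entries):
                raise FormatError(f"duplicate set name {name!r}", line=lineno)
            if len(entries) >= MAX_SETS:
                raise FormatError(
                    f"more than {MAX_SETS} set blocks", line=lineno
                )
            entries.append((name, []))
        elif line.strip():
            if not entries:
                raise FormatError("element line before any '>' set header", line=lineno)
            entries[-1][1].append(line)
    if not entries:
        raise FormatError("no set blocks found", line=len(lines) or 1)
    return build_family([(name, "\n".join(body)) for name, body in entries])


def read_sets_file(source: PathLike) -> SetFamily:
    """Read a sets file; elements are normalized exactly as typed input."""
    return parse_sets_file(Path(source).read_text(encoding="utf-8"))


def _iter_regions(table: RegionTable | QuotientRegionTable):
    if isinstance(table, QuotientRegionTable):
        for sig, code in zip(table.signatures(), table.codes()):
            yield code, table.regions[sig]
    else:
        for code in table.codes():
            yield code, table.regions[code]


def export_region_elements(
    table: RegionTable | QuotientRegionTable, directory: PathLike
) -> list[tuple[str, int]]:
    """Write one sorted element list per non-empty region.

    Files are named by the region's canonical code (``AB.txt``; quotient
    codes that touch a united group join group codes with ``_``, e.g.
    ``B_CD.txt``).  A ``manifest.tsv`` of ``filename<TAB>count`` rows is
    written alongside; the manifest is also returned.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, int]] = []
    for code, elements in _iter_regions(table):
        if not elements:
            continue
        fname = f"{code}.txt"
        _atomic_write_text(directory / fname, "\n".join(sorted(elements)) + "\n")
        manifest.append((fname, len(elements)))
    _atomic_write_text(
        directory / "manifest.tsv",
        "".join(f"{fname}\t{count}\n" for fname, count in manifest),
    )
    return manifest


def export_counts(
    table: RegionTable | QuotientRegionTable, destination: PathLike
) -> None:
    """Write a TSV of ``region_code<TAB>count`` plus a TOTAL row."""
    rows = ["region_code\tcount"]
    total = 0
    for code, elements in _iter_regions(table):
        rows.append(f"{code}\t{len(elements)}")
        total += len(elements)
    rows.append(f"TOTAL\t{total}")
    _atomic_write_text(destination, "\n".join(rows) + "\n")
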