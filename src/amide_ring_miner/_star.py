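"""Minimal STAR-syntax tokenizer and loop extraction.

Supports the subset needed for assigned-chemical-shift and
distance-restraint files: ``data_`` blocks, ``save_`` frames, ``loop_``
/ ``stop_``, ``#`` comments, single/double-quoted values and
semicolon-delimited text blocks.  Not a dictionary-validating parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


@dataclass
class StarLoop:
    """One loop: ordered tag names plus rows of raw string values."""

    tags: list[str]
    rows: list[list[str]] = field(default_factory=list)

    def tag_index(self, *candidates: str) -> int | None:
        """Index of the first tag whose name part matches a candidate.

        Matching is case-insensitive on the portion after the final dot,
        so ``_Atom_chem_shift.Val`` matches candidate ``val``.
        """
        lowered = [t.rsplit(".", 1)[-1].lower() for t in self.tags]
        for cand in candidates:
            c = cand.lower()
            if c in lowered:
                return lowered.index(c)
        return None

    def category(self) -> str:
        """Lower-cased category part of the first tag (before the dot)."""
        if not self.tags:
            return ""
        head = self.tags[0]
        if "." in head:
            return head.split(".", 1)[0].lstrip("_").lower()
        return head.lstrip("_").lower()


def _tokenize(text: str) -> Iterator[str]:
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            # semicolon text block: gather until closing ';'
            block = [line[1:]]
            i += 1
            while i < n and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            i += 1  # skip closing ';'
            yield "\n".join(block)
            continue
        pos = 0
        ln = len(line)
        while pos < ln:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = pos + 1
                # closing quote must be followed by whitespace or EOL
                while end < ln:
                    if line[end] == ch and (end + 1 == ln or line[end + 1] in " \t"):
                        break
                    end += 1
                yield line[pos + 1 : end]
                pos = end + 1
            else:
                end = pos
                while end < ln and line[end] not in " \t":
                    end += 1
                yield line[pos:end]
                pos = end
        i += 1


def parse_loops(path: str | Path) -> list[StarLoop]:
    """Extract every loop from a STAR file, bare or save-frame-wrapped."""
    text = Path(path).read_text()
    loops: list[StarLoop] = []
    tokens = _tokenize(text)
    for tok in tokens:
        if tok.lower() != "loop_":
            continue
        tags: list[str] = []
        values: list[str] = []
        in_header = True
        for tok2 in tokens:
            low = tok2.lower()
            if low == "stop_":
                break
            if low.startswith(("data_", "save_", "loop_")) and not tok2.startswith("_"):
                break
            if tok2.startswith("_"):
                if in_header:
                    tags.append(tok2)
                    continue
                break  # tag after values: malformed; end loop
            in_header = False
            values.append(tok2)
        loop = StarLoop(tags=tags)
        ncol = len(tags)
        if ncol:
            for start in range(0, len(values) - ncol + 1, ncol):
                loop.rows.append(values[start : start + ncol])
        loops.append(loop)
    return loops


def data_block_name(path: str | Path) -> str | None:
    """Name of the first ``data_`` block, or None if the file has none."""
    for tok in _tokenize(Path(path).read_text()):
        if tok.lower().startswith("data_") and len(tok) > 5:
            return tok[5:]
    return None


def quote_value(value: str) -> str:
    """Quote a value for STAR output when needed."""
    if value == "" or any(c in value for c in " \t'\"#") or value.startswith("_"):
        if "'" not in value:
            return f"'{value}'"
        return f'"{value}"'
    return value
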