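"""Karyotype-string grammar for embryo CNV reports.

Embryo screening reports summarize a profile as a bracketed karyotype such
as ``[46, XX]``, ``[48, XY, +6, +20]``, ``[46, XX, -8mos]`` or
``[46, XY, +16q(q11.2->qter, ~47M)]``: a chromosome count, the sex
chromosomes, then one token per event.  Published reports vary
typographically (en-dash or Unicode minus for losses, ``∼`` for ``~``,
``→`` for ``->``, optional space before ``mos``); the parser accepts all
variants and the writer emits a single canonical ASCII form, so
parse→format is the identity on canonical strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome import chrom_sort_key


class KaryotypeParseError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """One chromosome abnormality: a whole-chromosome or segmental gain/loss."""

    chrom: str
    sign: int  # +1 gain, -1 loss
    mosaic: bool = False
    arm: str | None = None  # 'p'/'q' for segmental events
    origin: str | None = None  # band where the segment starts, e.g. 'q11.2'
    terminus: str | None = None  # 'pter' or 'qter'
    span_mb: float | None = None

    @property
    def segmental(self) -> bool:
        return self.arm is not None

    def format(self) -> str:
        s = "+" if self.sign > 0 else "-"
        out = f"{s}{self.chrom}"
        if self.segmental:
            out += self.arm
            inner = f"~{self.span_mb:g}M" if self.span_mb is not None else ""
            if self.origin is not None:
                inner = f"{self.origin}->{self.terminus or self.arm + 'ter'}, " + inner
            out += f"({inner})"
        if self.mosaic:
            out += "mos"
        return out


@dataclass
class KaryotypeString:
    """Parsed karyotype: chromosome count, sex chromosomes, event list."""

    count: int
    sex: str
    events: tuple[Event, ...] = field(default_factory=tuple)

    @property
    def text(self) -> str:
        return format_karyotype(self)

    @property
    def abnormal_chroms(self) -> frozenset[str]:
        return frozenset(e.chrom for e in self.events)


_SIGNS = {"+": 1, "-": -1, "–": -1, "−": -1}  # -, en dash, minus sign

_EVENT_RE = re.compile(
    r"""^(?P<sign>[+\-–−])
         (?P<chrom>\d{1,2}|X|Y)
         (?P<arm>[pq])?
         (?:\s*\(\s*
             (?:(?P<origin>[pq]\d+(?:\.\d+)*)\s*(?:→|->)\s*(?P<term>[pq]ter)\s*,\s*)?
             [~∼]\s*(?P<span>\d+(?:\.\d+)?)\s*M\s*
         \))?
         \s*(?P<mos>mos)?$""",
    re.VERBOSE,
)


def _split_top_level(body: str) -> list[str]:
    """Split on commas that are not inside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur).strip())
    return parts


def parse_event(token: str) -> Event:
    m = _EVENT_RE.match(token.strip())
    if not m:
        raise KaryotypeParseError(f"malformed karyotype event: {token!r}")
    arm = m.group("arm")
    span = m.group("span")
    chrom = m.group("chrom")
    if chrom not in ("X", "Y") and not 1 <= int(chrom) <= 22:
        raise KaryotypeParseError(f"unknown chromosome in event: {token!r}")
    if m.group("origin") and not arm:
        raise KaryotypeParseError(f"segmental event without arm: {token!r}")
    return Event(
        chrom=m.group("chrom"),
        sign=_SIGNS[m.group("sign")],
        mosaic=m.group("mos") is not None,
        arm=arm,
        origin=m.group("origin"),
        terminus=m.group("term"),
        span_mb=float(span) if span is not None else None,
    )


def parse_karyotype(text: str) -> KaryotypeString:
    """Parse a bracketed karyotype string, tolerating typographic variants."""
    stripped = text.strip()
    if not (stripped.startswith("[") and stripped.endswith("]")):
        raise KaryotypeParseError(f"karyotype must be bracketed: {text!r}")
    parts = _split_top_level(stripped[1:-1])
    if len(parts) < 2:
        raise KaryotypeParseError(f"karyotype needs count and sex: {text!r}")
    try:
        count = int(parts[0])
    except ValueError:
        raise KaryotypeParseError(f"malformed chromosome count: {parts[0]!r}") from None
    sex = parts[1]
    if sex not in ("XX", "XY"):
        raise KaryotypeParseError(f"malformed sex chromosomes: {sex!r}")
    events = tuple(parse_event(tok) for tok in parts[2:] if tok)
    return KaryotypeString(count=count, sex=sex, events=events)


def format_karyotype(k: KaryotypeString) -> str:
    toks = [str(k.count), k.sex]
    toks += [e.format() for e in sorted(k.events, key=lambda e: (chrom_sort_key(e.chrom), e.arm or ""))]
    return "[" + ", ".join(toks) + "]"


def expected_count(sex: str, events) -> int:
    """Chromosome count implied by the event list (46 ± full whole-chromosome events)."""
    return 46 + sum(e.sign for e in events if not e.segmental and not e.mosaic)
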