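"""TIGR array grammar: repeats, spacers, units, and lossless assembly/parsing.

A dual-repeat array is, on its transcribed strand::

    edge[p:]  (sA loop sB edge) * (n-1)  sA loop sB  edge[:p]  [terminator]

where ``edge`` and ``loop`` are the two alternating 8-12 nt repeats, ``sA``
and ``sB`` the two variable spacers of each unit, and ``p`` the processing
offset strictly inside the edge repeat.  Mature guides span mid-edge to
mid-edge, one repeat period each.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq import NucSeq, DNA_BASES, hamming, has_ambiguity

BOX_D_DNA = "TG"  # repeat 5' motif (box D, 'UG' in RNA)
BOX_C_DNA = "CCA"  # repeat 3' motif (box C)

REPEAT_LEN_RANGE = (8, 12)
SPACER_LEN_RANGE = (8, 12)

#: Deterministic rho-independent terminator cassettes: 8-bp stem, 4-nt loop,
#: 8-nt U-tract.  Variants differ only in their first base so a cassette can
#: always be chosen that does not coincidentally extend a trailing edge
#: repeat.  The first entry is the default used by :func:`assemble_array`.
TERMINATOR_CASSETTES = (
    "GCCGGCGC" + "GAAA" + "GCGCCGGC" + "TTTTTTTT",
    "ACCGGCGC" + "GAAA" + "GCGCCGGT" + "TTTTTTTT",
    "TCCGGCGC" + "GAAA" + "GCGCCGGA" + "TTTTTTTT",
    "CGCCGGCG" + "GAAA" + "CGCCGGCG" + "TTTTTTTT",
)
DEFAULT_TERMINATOR = TERMINATOR_CASSETTES[0]


class InvalidModelError(ValueError):
    """A repeat set or array model violates the grammar invariants."""


class ParseError(ValueError):
    """No consistent alternating repeat placement could be found."""


def _check_repeat(name: str, seq: str) -> None:
    lo, hi = REPEAT_LEN_RANGE
    if not (lo <= len(seq) <= hi):
        raise InvalidModelError(f"{name} length {len(seq)} outside {lo}-{hi}")
    if set(seq) - DNA_BASES:
        raise InvalidModelError(f"{name} contains non-ACGT characters: {seq}")


@dataclass
class RepeatSet:
    """The locus-constant half of an array genotype.

    ``processing_offset`` is the cut position inside the edge repeat
    (1 <= p < len(edge)); it defaults to ``len(edge) // 2`` so that mature
    units span exactly one repeat period.  When ``enforce_boxes`` is set,
    both repeats must carry box D ("TG") at their 5' end and box C ("CCA")
    at their 3' end on the coding strand.
    """

    edge_repeat: str
    loop_repeat: str
    spacer_len_a: int = 9
    spacer_len_b: int = 9
    processing_offset: int | None = None
    enforce_boxes: bool = False

    def __post_init__(self) -> None:
        self.edge_repeat = self.edge_repeat.upper()
        self.loop_repeat = self.loop_repeat.upper()
        _check_repeat("edge_repeat", self.edge_repeat)
        _check_repeat("loop_repeat", self.loop_repeat)
        lo, hi = SPACER_LEN_RANGE
        for name, val in (("spacer_len_a", self.spacer_len_a), ("spacer_len_b", self.spacer_len_b)):
            if not (lo <= val <= hi):
                raise InvalidModelError(f"{name}={val} outside {lo}-{hi}")
        if self.processing_offset is None:
            self.processing_offset = len(self.edge_repeat) // 2
        if not (1 <= self.processing_offset < len(self.edge_repeat)):
            raise InvalidModelError(
                f"processing_offset {self.processing_offset} not strictly inside edge repeat"
            )
        if self.enforce_boxes:
            for name, rep in (("edge_repeat", self.edge_repeat), ("loop_repeat", self.loop_repeat)):
                if not rep.startswith(BOX_D_DNA) or not rep.endswith(BOX_C_DNA):
                    raise InvalidModelError(
                        f"{name} must start 'TG' (box D) and end 'CCA' (box C): {rep}"
                    )

    @property
    def edge_len(self) -> int:
        return len(self.edge_repeat)

    @property
    def loop_len(self) -> int:
        return len(self.loop_repeat)


def unit_period(repeat_set: RepeatSet) -> int:
    """Repeat period of the array == length of one mature guide (nt)."""
    return (
        repeat_set.edge_len
        + repeat_set.loop_len
        + repeat_set.spacer_len_a
        + repeat_set.spacer_len_b
    )


@dataclass
class TIGRUnit:
    """One dual-spacer unit (1-based ``index`` within its array)."""

    index: int
    spacer_a: str
    spacer_b: str

    def __post_init__(self) -> None:
        self.spacer_a = self.spacer_a.upper()
        self.spacer_b = self.spacer_b.upper()
        for name, sp in (("spacer_a", self.spacer_a), ("spacer_b", self.spacer_b)):
            if set(sp) - DNA_BASES:
                raise InvalidModelError(f"{name} contains ambiguity codes: {sp}")


@dataclass
class TIGRArrayModel:
    """Full genotype of a dual-repeat array.

    ``leading_edge_len`` / ``trailing_edge_len`` are the truncated edge
    lengths retained at the array 5'/3' boundaries (defaults ``len(edge)-p``
    and ``p``); ``has_terminator`` records whether a rho-independent
    terminator cassette follows the body.  The terminator is not counted in
    :attr:`body_length`.
    """

    repeat_set: RepeatSet
    units: list[TIGRUnit]
    leading_edge_len: int | None = None
    trailing_edge_len: int | None = None
    has_terminator: bool = False

    def __post_init__(self) -> None:
        rs = self.repeat_set
        if self.leading_edge_len is None:
            self.leading_edge_len = rs.edge_len - rs.processing_offset
        if self.trailing_edge_len is None:
            self.trailing_edge_len = rs.processing_offset
        self.validate()

    def validate(self) -> None:
        rs = self.repeat_set
        if not self.units:
            raise InvalidModelError("array model requires >= 1 unit")
        if not (0 <= self.leading_edge_len <= rs.edge_len):
            raise InvalidModelError("leading_edge_len outside [0, len(edge)]")
        if not (0 <= self.trailing_edge_len <= rs.edge_len):
            raise InvalidModelError("trailing_edge_len outside [0, len(edge)]")
        for i, unit in enumerate(self.units, start=1):
            if unit.index != i:
                raise InvalidModelError(f"unit index {unit.index} != ordinal {i}")
            if len(unit.spacer_a) != rs.spacer_len_a:
                raise InvalidModelError(
                    f"unit {i}: spacer_a length {len(unit.spacer_a)} != {rs.spacer_len_a}"
                )
            if len(unit.spacer_b) != rs.spacer_len_b:
                raise InvalidModelError(
                    f"unit {i}: spacer_b length {len(unit.spacer_b)} != {rs.spacer_len_b}"
                )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def body_length(self) -> int:
        """Assembled array length excluding any terminator cassette."""
        rs = self.repeat_set
        inner = sum(
            rs.spacer_len_a + rs.loop_len + rs.spacer_len_b for _ in self.units
        )
        return (
            self.leading_edge_len
            + self.trailing_edge_len
            + inner
            + (self.n_units - 1) * rs.edge_len
        )


@dataclass
class TigRNA:
    """One mature guide: mid-edge | spacer A | loop | spacer B | mid-edge.

    All five parts are RNA strings; ``boxC_positions`` / ``boxD_positions``
    give the 0-based offsets of the two "CCA" / "UG" structural anchors
    within the full guide (positions are reported even when the source
    repeat set does not enforce box motifs).
    """

    id: str
    edge_3part: str
    spacer_a: str
    loop: str
    spacer_b: str
    edge_5part: str
    boxC_positions: tuple[int, int]
    boxD_positions: tuple[int, int]

    @property
    def seq(self) -> str:
        return self.edge_3part + self.spacer_a + self.loop + self.spacer_b + self.edge_5part

    def __len__(self) -> int:
        return len(self.seq)


def assemble_array(model: TIGRArrayModel, terminator: str | None = None) -> NucSeq:
    """Assemble the transcribed-strand DNA of an array model.

    Deterministic: the same model always yields the same sequence.  When
    ``model.has_terminator`` is set, the terminator cassette (default
    :data:`DEFAULT_TERMINATOR`) is appended after the trailing edge.
    """
    model.validate()
    rs = model.repeat_set
    edge = rs.edge_repeat
    parts = [edge[rs.edge_len - model.leading_edge_len:]]
    for i, unit in enumerate(model.units):
        parts.append(unit.spacer_a)
        parts.append(rs.loop_repeat)
        parts.append(unit.spacer_b)
        if i < model.n_units - 1:
            parts.append(edge)
    parts.append(edge[: model.trailing_edge_len])
    if model.has_terminator:
        parts.append(terminator if terminator is not None else DEFAULT_TERMINATOR)
    return NucSeq("tigr_array", "".join(parts), "dna")


@dataclass
class ParseResult:
    """Outcome of :func:`parse_array`.

    ``start``/``end`` delimit the array body within the parsed sequence;
    per-copy mismatch counts are reported for every full loop and edge copy
    (5' to 3').
    """

    model: TIGRArrayModel
    start: int
    end: int
    loop_mismatches: list[int]
    edge_mismatches: list[int]
    terminator_start: int | None = None


def _approx_positions(seq: str, pattern: str, max_mm: int) -> list[int]:
    out = []
    w = len(pattern)
    for i in range(len(seq) - w + 1):
        if hamming(seq[i : i + w], pattern) <= max_mm:
            out.append(i)
    return out


def _walk_units(
    seq: str, rs: RepeatSet, q0: int, max_mm: int
) -> tuple[list[TIGRUnit], list[int], list[int], int] | None:
    """Walk alternating units starting from a loop copy at ``q0``.

    Returns (units, loop_mms, edge_mms, pos_after_last_sB) or None.
    """
    e, l = rs.edge_len, rs.loop_len
    sa, sb = rs.spacer_len_a, rs.spacer_len_b
    edge, loop = rs.edge_repeat, rs.loop_repeat
    units: list[TIGRUnit] = []
    loop_mms: list[int] = []
    edge_mms: list[int] = []
    q = q0
    while True:
        if q - sa < 0 or q + l + sb > len(seq):
            return None
        spacer_a = seq[q - sa : q]
        loop_copy = seq[q : q + l]
        spacer_b = seq[q + l : q + l + sb]
        if has_ambiguity(spacer_a) or has_ambiguity(spacer_b) or has_ambiguity(loop_copy):
            return None
        mm = hamming(loop_copy, loop)
        if mm > max_mm:
            return None
        loop_mms.append(mm)
        units.append(TIGRUnit(len(units) + 1, spacer_a, spacer_b))
        pos_e = q + l + sb
        nxt_loop = pos_e + e + sa
        if (
            nxt_loop + l <= len(seq)
            and hamming(seq[pos_e : pos_e + e], edge) <= max_mm
            and hamming(seq[nxt_loop : nxt_loop + l], loop) <= max_mm
            and not has_ambiguity(seq[pos_e : pos_e + e])
        ):
            edge_mms.append(hamming(seq[pos_e : pos_e + e], edge))
            q = nxt_loop
            continue
        return units, loop_mms, edge_mms, pos_e


def _trailing_parse(seq: str, rs: RepeatSet, pos_e: int) -> tuple[int, bool, int | None]:
    """Determine trailing edge length and terminator presence after the last sB.

    Prefers a trailing length whose remainder is empty or an exact packaged
    terminator cassette; falls back to the maximal edge-prefix match plus the
    heuristic terminator predictor (lossless for assembled sequences).
    """
    edge = rs.edge_repeat
    t_max = 0
    for t in range(1, rs.edge_len + 1):
        if pos_e + t <= len(seq) and seq[pos_e : pos_e + t] == edge[:t]:
            t_max = t
        else:
            break
    for t in range(t_max, -1, -1):
        rest = seq[pos_e + t :]
        if not rest:
            return t, False, None
        if any(rest.startswith(cas) for cas in TERMINATOR_CASSETTES):
            return t, True, pos_e + t
    # fall back: heuristic terminator search in a short downstream window
    from .detect import predict_terminator  # local import to avoid a cycle

    rest = seq[pos_e + t_max :]
    hit = predict_terminator(NucSeq("tail", rest, "dna")) if len(rest) >= 12 else None
    if hit is not None and hit.start <= 3:
        return t_max, True, pos_e + t_max + hit.start
    return t_max, False, None


def parse_array(
    seq: NucSeq, repeat_set: RepeatSet, max_mismatch_per_copy: int = 0
) -> ParseResult:
    """Parse a sequence against known repeats into an array model.

    Locates repeat copies allowing up to ``max_mismatch_per_copy``
    substitutions each, recovers spacers verbatim, measures boundary
    truncations and records per-copy mismatch counts.  The parse maximizing
    the unit count (ties broken leftmost) is returned.
    """
    if seq.kind != "dna":
        raise ParseError("parse_array requires DNA input")
    s = seq.seq
    rs = repeat_set
    anchors = _approx_positions(s, rs.loop_repeat, max_mismatch_per_copy)
    best: tuple[int, int, tuple] | None = None  # (-units, start, payload)
    for q0 in anchors:
        if q0 - rs.spacer_len_a < 0:
            continue
        walked = _walk_units(s, rs, q0, max_mismatch_per_copy)
        if walked is None:
            continue
        units, loop_mms, edge_mms, pos_e = walked
        key = (-len(units), q0)
        if best is None or key < best[:2]:
            best = (*key, (units, loop_mms, edge_mms, pos_e, q0))
    if best is None:
        raise ParseError(
            f"no consistent alternating repeat placement in {seq.id} "
            f"(loop anchors tried: {len(anchors)})"
        )
    units, loop_mms, edge_mms, pos_e, q0 = best[2]
    e = rs.edge_len
    lead = 0
    for ell in range(1, e + 1):
        i = q0 - rs.spacer_len_a - ell
        if i < 0 or s[i : i + ell] != rs.edge_repeat[e - ell :]:
            break
        lead = ell
    trail, has_term, term_start = _trailing_parse(s, rs, pos_e)
    start = q0 - rs.spacer_len_a - lead
    model = TIGRArrayModel(
        repeat_set=rs,
        units=units,
        leading_edge_len=lead,
        trailing_edge_len=trail,
        has_terminator=has_term,
    )
    return ParseResult(
        model=model,
        start=start,
        end=pos_e + trail,
        loop_mismatches=loop_mms,
        edge_mismatches=edge_mms,
        terminator_start=term_start,
    )


# ---------------------------------------------------------------------------
# flat key=value config serialization

_CONFIG_FIELDS = (
    "edge_repeat",
    "loop_repeat",
    "spacer_len_a",
    "spacer_len_b",
    "processing_offset",
    "enforce_boxes",
)


def repeat_set_to_config(rs: RepeatSet) -> str:
    lines = [f"{name} = {getattr(rs, name)}" for name in _CONFIG_FIELDS]
    return "\n".join(lines) + "\n"


def repeat_set_from_config(text: str) -> RepeatSet:
    values: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        values[key] = val
    try:
        return RepeatSet(
            edge_repeat=values["edge_repeat"],
            loop_repeat=values["loop_repeat"],
            spacer_len_a=int(values.get("spacer_len_a", 9)),
            spacer_len_b=int(values.get("spacer_len_b", 9)),
            processing_offset=int(values["processing_offset"])
            if "processing_offset" in values
            else None,
            enforce_boxes=values.get("enforce_boxes", "False").lower()
            in ("1", "true", "yes"),
        )
    except KeyError as exc:
        raise ValueError(f"config missing required key: {exc}") from exc


def unit_layout(model: TIGRArrayModel) -> list[tuple[str, int, int, int | None]]:
    """Feature layout of the assembled body as (type, start, end, unit_index).

    Types: ``edge_repeat`` (including truncated boundary copies),
    ``spacer_A``, ``loop_repeat``, ``spacer_B``.  Coordinates are 0-based
    half-open within the array body.
    """
    rs = model.repeat_set
    feats: list[tuple[str, int, int, int | None]] = []
    pos = 0
    if model.leading_edge_len:
        feats.append(("edge_repeat", 0, model.leading_edge_len, None))
    pos = model.leading_edge_len
    for i, unit in enumerate(model.units, start=1):
        feats.append(("spacer_A", pos, pos + rs.spacer_len_a, i))
        pos += rs.spacer_len_a
        feats.append(("loop_repeat", pos, pos + rs.loop_len, i))
        pos += rs.loop_len
        feats.append(("spacer_B", pos, pos + rs.spacer_len_b, i))
        pos += rs.spacer_len_b
        if i < model.n_units:
            feats.append(("edge_repeat", pos, pos + rs.edge_len, i))
            pos += rs.edge_len
    if model.trailing_edge_len:
        feats.append(("edge_repeat", pos, pos + model.trailing_edge_len, None))
    return feats
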