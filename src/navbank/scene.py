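"""Instruction handling and the ``goto()`` tagging primitive.

This module emulates the *outcome* of the architecture's perception and
compositional parsing for the planning task, not its mechanisms: a scene is
already a :class:`~navbank.maps.NavigationMap`, and an instruction is a plain
token sequence.  Three steps prepare a planning episode:

1. :func:`load_instruction` maps the instruction token-per-cell into bank
   slots ``n = 0`` (reserved safety copy) and ``n = 1``.
2. :func:`parse_goto` applies the ``goto()`` primitive: every destination
   cell on the module-A map is tagged ``<"all">`` (or the single named
   object's cell), and the start cell is tagged ``<"back">``.
3. :func:`broadcast` copies the tagged module-A map into every non-reserved
   bank slot, stripping action words, so each module can plan independently.

Only the ``"go"`` action word is implemented, with its modifiers ``"all"``
and ``"back"``.  Words are matched by exact lowercase equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import StateError, UnsupportedPrimitiveError, ValidationError
from .maps import Coord, ModuleBank, NavigationMap, Tag, TagKind, copy_map

ACTION_WORDS = {"go"}
#: Words that modify "go" or are grammatical filler, never object features.
_STOPWORDS = {"go", "to", "the", "a", "and", "all", "back", "objects", "object"}


@dataclass
class Instruction:
    """An instruction as an ordered token sequence."""

    tokens: list[str]
    source_text: str = ""

    @classmethod
    def from_text(cls, text: str) -> "Instruction":
        return cls(tokens=text.lower().split(), source_text=text)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValidationError("instruction must contain at least one token")


def _instruction_map(instr: Instruction, dims: Coord, map_id: int) -> NavigationMap:
    """Lay the tokens out one per cell along the first row(s), linked in order."""
    m = NavigationMap(dims=dims, map_id=map_id)
    nx, ny, _ = dims
    if len(instr.tokens) > nx * ny:
        raise ValidationError(f"instruction of {len(instr.tokens)} tokens does not fit {dims}")
    for i, tok in enumerate(instr.tokens):
        coord: Coord = (i % nx, i // nx, 0)
        cell = m.cell(coord)
        cell.features.add(tok)
        if tok in ACTION_WORDS:
            cell.add_tag(Tag(TagKind.ACTION_WORD, tok))
        nxt = i + 1
        if nxt < len(instr.tokens):
            cell.links.append((map_id, (nxt % nx, nxt // nx, 0)))
    return m


def load_instruction(instr: Instruction, bank: ModuleBank) -> ModuleBank:
    """Place *instr* token-per-cell into bank slots 0 and 1; slot 0 stays reserved.

    The reserved copy in slot 0 survives the later broadcast, so the
    instruction is never lost even when the working slots are overwritten.
    """
    if bank.size < 2:
        raise ValidationError("bank needs at least 2 module-B slots")
    dims = bank.module_a.dims
    bank.slots[0] = _instruction_map(instr, dims, map_id=0)
    bank.slots[1] = _instruction_map(instr, dims, map_id=1)
    bank.reserved.add(0)
    return bank


def _loaded_tokens(bank: ModuleBank) -> list[str]:
    source = bank.slots[1] if bank.slots[1] is not None else bank.slots[0]
    if source is None:
        raise StateError("no instruction loaded")
    # Follow the cell layout order used by load_instruction.
    nx = source.dims[0]
    toks = []
    for coord in sorted(source.cells, key=lambda c: (c[2], c[1], c[0])):
        cell = source.cells[coord]
        if cell.features:
            toks.append(next(iter(cell.features)))
    return toks


def parse_goto(bank: ModuleBank) -> tuple[NavigationMap, int]:
    """Apply the ``goto()`` primitive to the module-A map.

    Tags every destination cell with ``<"all">`` (all object cells when the
    instruction says "all", otherwise the cell whose features match the named
    object), tags the start cell with ``<"back">`` when the instruction says
    "back", and records the triggering action word on the start cell.
    Idempotent: re-parsing adds no new tags.

    Returns the tagged module-A map and the number of destination cells.
    """
    tokens = _loaded_tokens(bank)
    if not tokens:
        raise ValidationError("empty instruction")
    action = next((t for t in tokens if t in ACTION_WORDS or t not in _STOPWORDS), tokens[0])
    if action not in ACTION_WORDS:
        raise UnsupportedPrimitiveError(f"no primitive for action word {action!r}")

    m = bank.module_a
    start = m.start_coord()
    if start is None:
        raise ValidationError("module A map has no start cell")

    if "all" in tokens:
        targets = m.object_coords()
    else:
        wanted = {t for t in tokens if t not in _STOPWORDS}
        targets = [c for c in m.object_coords() if wanted and wanted <= m.cells[c].features]
    for coord in targets:
        m.cells[coord].add_tag(Tag(TagKind.ALL_MARKER, "all"))
    if "back" in tokens:
        m.cells[start].add_tag(Tag(TagKind.BACK_MARKER, "back"))
    m.cells[start].add_tag(Tag(TagKind.ACTION_WORD, action))
    return m, len(targets)


def broadcast(bank: ModuleBank) -> ModuleBank:
    """Copy the tagged module-A map into every non-reserved slot.

    Each slot receives an independent deep copy with action words stripped:
    only the tagged cells to navigate remain.  Slot 0 (and any other
    reserved slot) is untouched.
    """
    if not bank.module_a.tagged_coords(TagKind.ALL_MARKER):
        raise StateError("parse_goto must tag the module A map before broadcast")
    for n in bank.working_indices():
        m = copy_map(bank.module_a, strip_action_words=True)
        m.map_id = n
        bank.slots[n] = m
    return bank
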