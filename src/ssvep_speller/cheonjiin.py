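"""Cheonjiin keyboard engine: grid navigation, multi-tap composition, planning.

The Cheonjiin layout builds every Korean vowel from three elements —
heaven (ㆍ), earth (ㅡ) and human (ㅣ) — and cycles consonants by repeated
presses of one key (ㄱ→ㅋ→ㄲ, ㄴ→ㄹ, ...).  Under the speller's five-command
alphabet {UP, DOWN, LEFT, RIGHT, SELECT}, a cursor walks a 4x4 grid of 14
keys and SELECT presses the key under it.  This module implements:

* the keyboard layout (JSON data file, swappable);
* cursor movement with edge clamping and skip-through over empty cells;
* the Hangul composition automaton (syllable = initial L + medial V +
  optional final T, with multi-tap cycling, vowel-element resolution,
  final-consonant stealing and compound finals);
* Unicode syllable assembly (0xAC00 + (L*21 + V)*28 + T);
* a typing planner that turns target text into a command sequence with
  BFS-shortest cursor paths, reporting movement and selection counts
  separately (the keystroke-economy analyzer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .commands import Command

# ---------------------------------------------------------------------------
# Jamo inventories (Unicode compatibility jamo as identifiers)
# ---------------------------------------------------------------------------

INITIALS = tuple("ㄱㄲㄴㄷㄸㄹㅁㅂㅃㅅㅆㅇㅈㅉㅊㅋㅌㅍㅎ")  # 19, U+1100 order
MEDIALS = tuple("ㅏㅐㅑㅒㅓㅔㅕㅖㅗㅘㅙㅚㅛㅜㅝㅞㅟㅠㅡㅢㅣ")  # 21, U+1161 order
FINALS = ("",) + tuple("ㄱㄲㄳㄴㄵㄶㄷㄹㄺㄻㄼㄽㄾㄿㅀㅁㅂㅄㅅㅆㅇㅈㅊㅋㅌㅍㅎ")  # 28

COMPOUND_FINALS = {
    "ㄳ": ("ㄱ", "ㅅ"), "ㄵ": ("ㄴ", "ㅈ"), "ㄶ": ("ㄴ", "ㅎ"),
    "ㄺ": ("ㄹ", "ㄱ"), "ㄻ": ("ㄹ", "ㅁ"), "ㄼ": ("ㄹ", "ㅂ"),
    "ㄽ": ("ㄹ", "ㅅ"), "ㄾ": ("ㄹ", "ㅌ"), "ㄿ": ("ㄹ", "ㅍ"),
    "ㅀ": ("ㄹ", "ㅎ"), "ㅄ": ("ㅂ", "ㅅ"),
}
_COMPOUND_FROM_PARTS = {v: k for k, v in COMPOUND_FINALS.items()}

COMPOUND_MEDIALS = {
    "ㅘ": ("ㅗ", "ㅏ"), "ㅙ": ("ㅗ", "ㅐ"), "ㅚ": ("ㅗ", "ㅣ"),
    "ㅝ": ("ㅜ", "ㅓ"), "ㅞ": ("ㅜ", "ㅔ"), "ㅟ": ("ㅜ", "ㅣ"),
    "ㅢ": ("ㅡ", "ㅣ"),
}

# Vowel-element composition table: press sequence over {ㅣ, ㆍ, ㅡ} -> medial.
# Compounds concatenate their constituents' sequences (ㅚ = ㅗ + ㅣ, ...).
VOWEL_TABLE: dict[tuple[str, ...], str] = {
    ("ㅣ",): "ㅣ",
    ("ㅡ",): "ㅡ",
    ("ㅣ", "ㆍ"): "ㅏ",
    ("ㅣ", "ㆍ", "ㆍ"): "ㅑ",
    ("ㆍ", "ㅣ"): "ㅓ",
    ("ㆍ", "ㆍ", "ㅣ"): "ㅕ",
    ("ㆍ", "ㅡ"): "ㅗ",
    ("ㆍ", "ㆍ", "ㅡ"): "ㅛ",
    ("ㅡ", "ㆍ"): "ㅜ",
    ("ㅡ", "ㆍ", "ㆍ"): "ㅠ",
    ("ㅣ", "ㆍ", "ㅣ"): "ㅐ",
    ("ㅣ", "ㆍ", "ㆍ", "ㅣ"): "ㅒ",
    ("ㆍ", "ㅣ", "ㅣ"): "ㅔ",
    ("ㆍ", "ㆍ", "ㅣ", "ㅣ"): "ㅖ",
    ("ㅡ", "ㅣ"): "ㅢ",
    ("ㆍ", "ㅡ", "ㅣ"): "ㅚ",
    ("ㅡ", "ㆍ", "ㅣ"): "ㅟ",
    ("ㆍ", "ㅡ", "ㅣ", "ㆍ"): "ㅘ",
    ("ㆍ", "ㅡ", "ㅣ", "ㆍ", "ㅣ"): "ㅙ",
    ("ㅡ", "ㆍ", "ㆍ", "ㅣ"): "ㅝ",
    ("ㅡ", "ㆍ", "ㆍ", "ㅣ", "ㅣ"): "ㅞ",
}
MEDIAL_TO_ELEMENTS = {v: k for k, v in VOWEL_TABLE.items()}
_VOWEL_PREFIXES = {seq[:i] for seq in VOWEL_TABLE for i in range(1, len(seq) + 1)}

_L_INDEX = {j: i for i, j in enumerate(INITIALS)}
_V_INDEX = {j: i for i, j in enumerate(MEDIALS)}
_T_INDEX = {j: i for i, j in enumerate(FINALS)}
HANGUL_BASE = 0xAC00


def resolve_vowel(elements) -> tuple[str | None, bool]:
    """Resolve an element sequence to ``(medial or None, is_valid_state)``.

    Returns the medial when the sequence is a complete table row, ``None``
    when it is only a prefix of one; ``is_valid_state`` is False when the
    sequence matches no table prefix at all (the caller then commits the
    previous vowel and starts a new one).
    """
    seq = tuple(elements)
    if not seq:
        raise ValueError("empty element sequence")
    if seq in VOWEL_TABLE:
        return VOWEL_TABLE[seq], True
    return None, seq in _VOWEL_PREFIXES


def compose_syllable(initial: str, medial: str, final: str | None = None) -> str:
    """Precomposed Hangul syllable via the Unicode composition formula."""
    if initial not in _L_INDEX:
        raise ValueError(f"{initial!r} is not a valid initial consonant")
    if medial not in _V_INDEX:
        raise ValueError(f"{medial!r} is not a valid medial vowel")
    t = final or ""
    if t not in _T_INDEX:
        raise ValueError(f"{final!r} is not a valid final consonant")
    code = HANGUL_BASE + (_L_INDEX[initial] * 21 + _V_INDEX[medial]) * 28 + _T_INDEX[t]
    return chr(code)


def decompose_syllable(char: str) -> tuple[str, str, str | None]:
    """Inverse of :func:`compose_syllable` for a precomposed syllable."""
    code = ord(char) - HANGUL_BASE
    if not 0 <= code < 19 * 21 * 28:
        raise ValueError(f"{char!r} is not a precomposed Hangul syllable")
    t = code % 28
    v = (code // 28) % 21
    l = code // (28 * 21)
    return INITIALS[l], MEDIALS[v], FINALS[t] or None


def _combine_final(parts: list[str]) -> str | None:
    """Final-consonant components -> final jamo, or None if not a legal final."""
    if not parts:
        return ""
    if len(parts) == 1:
        return parts[0] if parts[0] in _T_INDEX else None
    if len(parts) == 2:
        return _COMPOUND_FROM_PARTS.get(tuple(parts))
    return None


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Key:
    kind: str  # "consonant" | "vowel" | "function"
    taps: tuple[str, ...]
    label: str


@dataclass(frozen=True)
class KeyboardLayout:
    name: str
    kind: str  # "cheonjiin" | "direct"
    grid: tuple[tuple[Key | None, ...], ...]
    home: tuple[int, int]

    @property
    def n_rows(self) -> int:
        return len(self.grid)

    @property
    def n_cols(self) -> int:
        return len(self.grid[0])

    @property
    def n_keys(self) -> int:
        return sum(1 for row in self.grid for k in row if k is not None)

    def key_at(self, pos) -> Key | None:
        r, c = pos
        return self.grid[r][c]

    def positions(self):
        return [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if self.grid[r][c] is not None
        ]

    def find_jamo(self, jamo: str) -> tuple[tuple[int, int], int]:
        """Position and tap index of the key producing ``jamo``."""
        for r, row in enumerate(self.grid):
            for c, key in enumerate(row):
                if key is not None and key.kind != "function" and jamo in key.taps:
                    return (r, c), key.taps.index(jamo)
        raise KeyError(f"jamo {jamo!r} is not reachable on layout {self.name}")

    def find_function(self, name: str) -> tuple[int, int]:
        for r, row in enumerate(self.grid):
            for c, key in enumerate(row):
                if key is not None and key.kind == "function" and key.taps[0] == name:
                    return (r, c)
        raise KeyError(f"function key {name!r} not on layout {self.name}")


def _layout_from_dict(d: dict) -> KeyboardLayout:
    grid = tuple(
        tuple(
            Key(kind=cell["kind"], taps=tuple(cell["taps"]), label=cell["label"])
            if cell is not None
            else None
            for cell in row
        )
        for row in d["grid"]
    )
    return KeyboardLayout(
        name=d["name"], kind=d["kind"], grid=grid, home=tuple(d["home"])
    )


def load_layout(path_or_name) -> KeyboardLayout:
    """Load a layout from a JSON file path or a bundled data-file name."""
    try:
        text = resources.files("ssvep_speller.data").joinpath(str(path_or_name)).read_text("utf-8")
    except (FileNotFoundError, ModuleNotFoundError):
        with open(path_or_name, encoding="utf-8") as fh:
            text = fh.read()
    return _layout_from_dict(json.loads(text))


def default_layout() -> KeyboardLayout:
    """The bundled 14-key Cheonjiin grid (row 0 = ㅣ, ㆍ, ㅡ, DELETE)."""
    return load_layout("cheonjiin_layout.json")


def qwerty_layout() -> KeyboardLayout:
    """Synthetic QWERTY (2-beolsik) grid fixture for movement-cost comparison."""
    return load_layout("qwerty_layout.json")


# ---------------------------------------------------------------------------
# Cursor
# ---------------------------------------------------------------------------

_DIRS = {
    Command.UP: (-1, 0),
    Command.DOWN: (1, 0),
    Command.LEFT: (0, -1),
    Command.RIGHT: (0, 1),
}

MOVE_COMMANDS = tuple(_DIRS)


@dataclass
class CursorState:
    position: tuple[int, int]
    selection_history: list = field(default_factory=list)


def move_cursor(
    layout: KeyboardLayout, position, direction: Command, wrap: bool = False
):
    """One cursor step: clamp at edges, skip through empty cells.

    The cursor keeps moving in ``direction`` over empty cells; if it runs
    off the grid (or, with ``wrap=True``, returns to its start) it stays
    where it was.
    """
    if direction not in _DIRS:
        raise ValueError(f"{direction} is not a movement command")
    dr, dc = _DIRS[direction]
    r, c = position
    for _ in range(max(layout.n_rows, layout.n_cols)):
        r, c = r + dr, c + dc
        if wrap:
            r %= layout.n_rows
            c %= layout.n_cols
            if (r, c) == tuple(position):
                break
        elif not (0 <= r < layout.n_rows and 0 <= c < layout.n_cols):
            break
        if layout.grid[r][c] is not None:
            return (r, c)
    return tuple(position)


def _movement_graph(layout: KeyboardLayout, wrap: bool = False):
    """pos -> {direction: resulting pos} for all productive moves."""
    graph = {}
    for pos in layout.positions():
        edges = {}
        for d in MOVE_COMMANDS:
            nxt = move_cursor(layout, pos, d, wrap=wrap)
            if nxt != pos:
                edges[d] = nxt
        graph[pos] = edges
    return graph


def shortest_path(
    layout: KeyboardLayout, start, goal, wrap: bool = False
) -> list[Command]:
    """BFS-shortest command path between two keys (deterministic tie-break)."""
    start, goal = tuple(start), tuple(goal)
    if layout.key_at(start) is None or layout.key_at(goal) is None:
        raise ValueError("start/goal must be non-empty cells")
    if start == goal:
        return []
    graph = _movement_graph(layout, wrap=wrap)
    frontier = [start]
    came: dict = {start: None}
    while frontier:
        nxt_frontier = []
        for pos in frontier:
            for d in MOVE_COMMANDS:
                if d not in graph[pos]:
                    continue
                np_ = graph[pos][d]
                if np_ in came:
                    continue
                came[np_] = (pos, d)
                if np_ == goal:
                    path = []
                    cur = np_
                    while came[cur] is not None:
                        prev, dd = came[cur]
                        path.append(dd)
                        cur = prev
                    return path[::-1]
                nxt_frontier.append(np_)
        frontier = nxt_frontier
    raise ValueError(f"no path from {start} to {goal} on {layout.name}")


# ---------------------------------------------------------------------------
# Composition automaton
# ---------------------------------------------------------------------------

class Composer:
    """Hangul composition state machine for Cheonjiin key presses.

    Pending state is (initial L, vowel element sequence, final component
    list); ``text`` renders committed text plus the pending preview.
    Multi-tap cycling is armed by a consonant press and broken by any other
    key or by cursor movement (:meth:`break_multitap`) — there is no dwell
    timeout, since the BCI has no key-up events.
    """

    def __init__(self):
        self.committed: list[str] = []
        self.L: str | None = None
        self.vseq: list[str] = []
        self.T: list[str] = []
        self._tap_key: Key | None = None  # armed multi-tap key
        self._tap_idx: int = 0
        self._tap_loc: str | None = None  # "L" or "T"

    # -- rendering ---------------------------------------------------------

    @property
    def medial(self) -> str | None:
        if not self.vseq:
            return None
        return resolve_vowel(self.vseq)[0]

    def _render_pending(self) -> str:
        v = self.medial
        t = _combine_final(self.T)
        if self.L is not None and v is not None:
            return compose_syllable(self.L, v, t or None)
        parts = ""
        if self.L is not None:
            parts += self.L
        if v is not None:
            parts += v
        elif self.vseq:
            parts += "".join(self.vseq)
        return parts

    @property
    def text(self) -> str:
        return "".join(self.committed) + self._render_pending()

    # -- internals ---------------------------------------------------------

    def _commit_pending(self):
        s = self._render_pending()
        if s:
            self.committed.append(s)
        self.L, self.vseq, self.T = None, [], []
        self._tap_loc = None

    def break_multitap(self):
        """Freeze the active multi-tap cycle (cursor moved)."""
        self._tap_key = None
        self._tap_loc = None

    def _insert_consonant(self, jamo: str):
        v = self.medial
        if self.L is not None and v is not None:
            candidate = _combine_final(self.T + [jamo])
            if candidate:
                self.T.append(jamo)
                self._tap_loc = "T"
                return
        # anything else starts a new syllable with this consonant as initial
        self._commit_pending()
        self.L = jamo
        self._tap_loc = "L"

    def _advance_cycle(self, key: Key):
        self._tap_idx = (self._tap_idx + 1) % len(key.taps)
        jamo = key.taps[self._tap_idx]
        if self._tap_loc == "L":
            # A bare initial that the previous tap split off the preceding
            # syllable may re-merge once the cycle reaches a jamo that is
            # legal in that syllable's final slot (e.g. 옐 + ㅇ -> 옐ㅇ,
            # next tap ㅁ -> 옒), mirroring phone IME behaviour.
            if not self.vseq and not self.T and self.committed:
                try:
                    l_prev, v_prev, t_prev = decompose_syllable(self.committed[-1])
                except ValueError:
                    pass
                else:
                    parts = list(COMPOUND_FINALS.get(t_prev, (t_prev,))) if t_prev else []
                    if _combine_final(parts + [jamo]):
                        self.committed.pop()
                        self.L, self.T = l_prev, parts + [jamo]
                        self.vseq = list(MEDIAL_TO_ELEMENTS[v_prev])
                        self._tap_loc = "T"
                        return
            self.L = jamo
            return
        # cycling a final: detach to a new syllable if it stops being legal
        base = self.T[:-1]
        if _combine_final(base + [jamo]):
            self.T[-1] = jamo
        else:
            self.T = base
            self._commit_pending()
            self.L = jamo
            self._tap_loc = "L"

    def _insert_vowel_element(self, elem: str):
        if self.T:
            # the final consonant is stolen as the next syllable's initial
            stolen = self.T.pop()
            self._commit_pending()
            self.L = stolen
            self.vseq = [elem]
            return
        if self.vseq:
            cand = self.vseq + [elem]
            _, ok = resolve_vowel(cand)
            if ok:
                self.vseq = cand
            else:
                self._commit_pending()
                self.vseq = [elem]
        else:
            self.vseq = [elem]

    # -- public press interface -------------------------------------------

    def press_key(self, key: Key):
        """Apply one key press (the SELECT action on the key under the cursor)."""
        if key.kind == "consonant":
            if self._tap_key is key and self._tap_loc is not None and len(key.taps) > 1:
                self._advance_cycle(key)
            else:
                self._insert_consonant(key.taps[0])
                self._tap_idx = 0
            self._tap_key = key
            return
        # any non-consonant press commits the multi-tap cycle
        self._tap_key = None
        if key.kind == "vowel":
            self._insert_vowel_element(key.taps[0])
            self._tap_loc = None
            return
        if key.kind == "function":
            name = key.taps[0]
            if name == "DELETE":
                self.delete()
            elif name == "SPACE":
                self._commit_pending()
                self.committed.append(" ")
            elif name == "ENTER":
                self._commit_pending()
            elif name == "PERIOD":
                self._commit_pending()
                self.committed.append(".")
            else:
                raise ValueError(f"unknown function key {name!r}")
            return
        raise ValueError(f"unknown key kind {key.kind!r}")

    def delete(self):
        """Remove the most recently entered jamo/element."""
        self._tap_key = None
        self._tap_loc = None
        if self.T:
            self.T.pop()
        elif self.vseq:
            self.vseq.pop()
        elif self.L is not None:
            self.L = None
        elif self.committed:
            last = self.committed.pop()
            if len(last) > 1:  # multi-char committed chunk: trim one char
                self.committed.append(last[:-1])


def press_sequence(layout: KeyboardLayout, jamo_or_functions) -> str:
    """Convenience: apply presses named by jamo/function, return the text."""
    comp = Composer()
    prev_pos = None
    for name in jamo_or_functions:
        if name in ("DELETE", "SPACE", "ENTER", "PERIOD"):
            pos = layout.find_function(name)
        else:
            pos, _ = layout.find_jamo(name)
        if prev_pos is not None and pos != prev_pos:
            pass  # different key; press_key handles multitap commit
        comp.press_key(layout.key_at(pos))
        prev_pos = pos
    return comp.text


# ---------------------------------------------------------------------------
# Command replay
# ---------------------------------------------------------------------------

def execute_commands(
    layout: KeyboardLayout, commands, start=None, wrap: bool = False
) -> tuple[str, CursorState]:
    """Deterministically replay a command sequence into text.

    Movement commands move the cursor (breaking any armed multi-tap);
    SELECT presses the key under the cursor.  Returns the final text
    (committed plus pending preview) and the cursor state.
    """
    cursor = CursorState(position=tuple(start) if start is not None else layout.home)
    comp = Composer()
    for cmd in commands:
        cmd = Command(cmd)
        if cmd in _DIRS:
            cursor.position = move_cursor(layout, cursor.position, cmd, wrap=wrap)
            comp.break_multitap()
        elif cmd == Command.SELECT:
            key = layout.key_at(cursor.position)
            if key is None:
                raise RuntimeError("cursor on an empty cell")
            comp.press_key(key)
            cursor.selection_history.append(cursor.position)
        elif cmd == Command.NONE:
            continue
        else:
            raise ValueError(f"cannot execute {cmd}")
    return comp.text, cursor


# ---------------------------------------------------------------------------
# Typing planner / keystroke-economy analyzer
# ---------------------------------------------------------------------------

@dataclass
class TypingPlan:
    commands: list[Command]
    movements: int
    selects: int
    layout_name: str
    start: tuple[int, int]

    @property
    def total(self) -> int:
        return self.movements + self.selects


def _press_units(layout: KeyboardLayout, text: str, enter_each_syllable: bool):
    """Decompose text into (position, n_taps, is_consonant) press units."""
    units = []

    def jamo_unit(jamo: str):
        pos, idx = layout.find_jamo(jamo)
        key = layout.key_at(pos)
        units.append((pos, idx + 1, key.kind == "consonant"))

    def medial_units(v: str):
        if layout.kind == "cheonjiin":
            for elem in MEDIAL_TO_ELEMENTS[v]:
                jamo_unit(elem)
        else:
            try:
                jamo_unit(v)
            except KeyError:
                a, b = COMPOUND_MEDIALS[v]
                jamo_unit(a)
                medial_units(b)

    for ch in text:
        if ch == " ":
            units.append((layout.find_function("SPACE"), 1, False))
            continue
        if ch == ".":
            units.append((layout.find_function("PERIOD"), 1, False))
            continue
        code = ord(ch) - HANGUL_BASE
        if 0 <= code < 19 * 21 * 28:
            l, v, t = decompose_syllable(ch)
            jamo_unit(l)
            medial_units(v)
            if t:
                for part in COMPOUND_FINALS.get(t, (t,)):
                    jamo_unit(part)
            if enter_each_syllable:
                units.append((layout.find_function("ENTER"), 1, False))
            continue
        if ch in _L_INDEX or ch in ("ㄸ", "ㅃ", "ㅉ"):
            jamo_unit(ch)
            continue
        if ch in _V_INDEX:
            medial_units(ch)
            continue
        raise ValueError(f"character {ch!r} cannot be typed on layout {layout.name}")
    return units


def type_text_plan(
    text: str,
    layout: KeyboardLayout | None = None,
    start=None,
    wrap: bool = False,
    enter_each_syllable: bool = False,
) -> TypingPlan:
    """Plan the command sequence that types ``text`` from ``start``.

    Between consecutive presses the cursor takes a BFS-shortest path on the
    key grid; each tap is one SELECT.  When two separate consonant jamo
    fall on the same key back to back (e.g. 안 followed by 녕), a minimal
    two-move detour is inserted to break the multi-tap cycle.  Movement and
    selection counts are reported separately so either keystroke-counting
    convention can be used.
    """
    layout = layout or default_layout()
    pos = tuple(start) if start is not None else layout.home
    units = _press_units(layout, text, enter_each_syllable)
    commands: list[Command] = []
    movements = selects = 0
    prev_consonant_pos = None
    for target, n_taps, is_consonant in units:
        if is_consonant and prev_consonant_pos == target and pos == target:
            # break the armed multi-tap: step to any neighbor and back
            graph = _movement_graph(layout, wrap=wrap)
            d, nxt = next(iter(graph[pos].items()))
            commands.append(d)
            back = shortest_path(layout, nxt, pos, wrap=wrap)
            commands.extend(back)
            movements += 1 + len(back)
        path = shortest_path(layout, pos, target, wrap=wrap)
        commands.extend(path)
        movements += len(path)
        pos = target
        commands.extend([Command.SELECT] * n_taps)
        selects += n_taps
        prev_consonant_pos = target if is_consonant else None
    return TypingPlan(
        commands=commands,
        movements=movements,
        selects=selects,
        layout_name=layout.name,
        start=tuple(start) if start is not None else layout.home,
    )


def movement_cost(
    text: str, layout: KeyboardLayout | None = None, start=None
) -> dict:
    """Keystroke-economy summary for typing ``text`` on a layout."""
    plan = type_text_plan(text, layout=layout, start=start)
    return {
        "layout": plan.layout_name,
        "start": plan.start,
        "movements": plan.movements,
        "selects": plan.selects,
        "movements_plus_selects": plan.total,
    }
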