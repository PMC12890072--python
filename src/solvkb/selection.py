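"""A small selection language over atom records.

Selections are boolean expressions over the declared atom fields::

    role=backbone
    polarity_class in {polar_charged, polar_uncharged} and role=sidechain
    residue_index=120:152 or residue_name=TFE
    not element=H

Supported fields: ``atom_name``, ``element``, ``residue_index``,
``residue_name``, ``role``, ``polarity_class``.  Operators: ``=``
(alias ``==``), ``!=``, ``in {v1, v2, ...}``; ``residue_index`` also
accepts inclusive ranges ``lo:hi``.  ``and``/``or``/``not`` and
parentheses combine predicates.  The result is a sorted, duplicate-free
tuple of atom indices, so selections are deterministic and
order-independent.
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

from .model import AtomRecord, PolarityClass, Role, SolvationSystem

FIELDS = ("atom_name", "element", "residue_index", "residue_name", "role", "polarity_class")

_ENUM_FIELDS = {
    "role": {r.value for r in Role},
    "polarity_class": {p.value for p in PolarityClass},
}


class SelectionError(ValueError):
    """Raised for syntactically or semantically invalid selections."""


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<op>!=|==|=|\(|\)|\{|\}|,)|(?P<word>[A-Za-z0-9_:/\.\-']+))"
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise SelectionError(f"cannot tokenize selection at: {text[pos:]!r}")
            break
        tokens.append(m.group("op") or m.group("word"))
        pos = m.end()
    return tokens


Predicate = Callable[[AtomRecord], bool]


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection")
        self.pos += 1
        return tok

    def parse(self) -> Predicate:
        pred = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return pred

    def expr(self) -> Predicate:
        left = self.term()
        while self.peek() in ("or", "|"):
            self.take()
            right = self.term()
            left = (lambda a, l=left, r=right: l(a) or r(a))
        return left

    def term(self) -> Predicate:
        left = self.factor()
        while self.peek() in ("and", "&"):
            self.take()
            right = self.factor()
            left = (lambda a, l=left, r=right: l(a) and r(a))
        return left

    def factor(self) -> Predicate:
        tok = self.peek()
        if tok == "not":
            self.take()
            inner = self.factor()
            return lambda a: not inner(a)
        if tok == "(":
            self.take()
            inner = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return inner
        return self.predicate()

    def predicate(self) -> Predicate:
        field = self.take()
        if field not in FIELDS:
            raise SelectionError(f"unknown field {field!r}; expected one of {FIELDS}")
        op = self.take()
        if op in ("=", "=="):
            value = self.take()
            return self._compare(field, [value], negate=False)
        if op == "!=":
            value = self.take()
            return self._compare(field, [value], negate=True)
        if op == "in":
            values = self._value_list()
            return self._compare(field, values, negate=False)
        raise SelectionError(f"unknown operator {op!r} after field {field!r}")

    def _value_list(self) -> list[str]:
        values: list[str] = []
        braced = self.peek() == "{"
        if braced:
            self.take()
        while True:
            values.append(self.take())
            if self.peek() == ",":
                self.take()
                continue
            break
        if braced:
            if self.take() != "}":
                raise SelectionError("unbalanced braces in value list")
        if not values:
            raise SelectionError("empty value list")
        return values

    def _compare(self, field: str, values: list[str], negate: bool) -> Predicate:
        if field == "residue_index":
            tests = [_index_test(v) for v in values]

            def pred(a: AtomRecord) -> bool:
                hit = any(t(a.residue_index) for t in tests)
                return not hit if negate else hit

            return pred

        if field in _ENUM_FIELDS:
            allowed = _ENUM_FIELDS[field]
            for v in values:
                if v not in allowed:
                    raise SelectionError(
                        f"unknown value {v!r} for {field}; expected one of {sorted(allowed)}"
                    )
        value_set = {v.upper() for v in values} if field in ("atom_name", "element", "residue_name") else set(values)

        def pred(a: AtomRecord) -> bool:
            raw = getattr(a, field)
            raw = raw.value if isinstance(raw, (Role, PolarityClass)) else str(raw).upper()
            hit = raw in value_set
            return not hit if negate else hit

        return pred


def _index_test(value: str) -> Callable[[int], bool]:
    if ":" in value:
        lo_s, hi_s = value.split(":", 1)
        try:
            lo, hi = int(lo_s), int(hi_s)
        except ValueError as exc:
            raise SelectionError(f"bad residue_index range {value!r}") from exc
        return lambda i: lo <= i <= hi
    try:
        target = int(value)
    except ValueError as exc:
        raise SelectionError(f"bad residue_index value {value!r}") from exc
    return lambda i: i == target


def compile_selection(selection: str) -> Predicate:
    """Compile a selection expression into a predicate over AtomRecord."""
    tokens = _tokenize(selection)
    if not tokens:
        raise SelectionError("empty selection")
    return _Parser(tokens).parse()


def select_atoms(atoms: Sequence[AtomRecord], selection: str) -> tuple[int, ...]:
    """Indices (sorted, unique) of atoms matching a selection expression."""
    pred = compile_selection(selection)
    return tuple(i for i, a in enumerate(atoms) if pred(a))


def select_group(system: SolvationSystem, selection: str) -> tuple[int, ...]:
    """Select solute atoms of a system by expression; see module docstring."""
    return select_atoms(system.solute_atoms, selection)
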