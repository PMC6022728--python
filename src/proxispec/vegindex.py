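"""Vegetation-index registry, band-math language, and index evaluation.

An index formula is a closed-form arithmetic expression over terms
``R<nm>`` (reflectance at an integer wavelength), numeric literals,
``+ - * /`` (the typographic ``×``/``÷``/``−`` are accepted as aliases) and
parentheses, e.g. ``(R800-R670)/(R800+R670)`` for NDVI.

Evaluation is strict about bands: an index is computed for a sample only if
*every* wavelength the formula references is present on the collection's
grid — there is no nearest-neighbour fallback and no interpolation, so a
missing band yields a missing value rather than a silently shifted one.
Division by zero likewise yields a missing value instead of aborting a
140-column sweep.

The bundled registry (``data/vegetation_indices.tsv``) carries 140 indices
with literature references, covering chlorophyll, pigment-ratio, structure,
red-edge, stress/disease and water-status indices in the 400–1,000 nm
range.  Users can append their own definitions from an extra registry file
or directly from expression text via :func:`parse_formula`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SpectralCollection
from .errors import FormulaSyntaxError, RegistryError

__all__ = [
    "VegetationIndexDefinition",
    "IndexResult",
    "parse_formula",
    "load_registry",
    "evaluate_index",
    "evaluate_all",
    "VALID_BAND_RANGE_NM",
]

VALID_BAND_RANGE_NM = (400, 1000)

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<band>R\d+)"
    r"|(?P<number>\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?"
    r"|(?P<op>[+\-*/()×÷−])"
    r"|(?P<bad>\S))"
)

_OP_ALIASES = {"×": "*", "÷": "/", "−": "-"}


def _tokenize(text: str) -> list[tuple[str, object, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        if m.group("bad"):
            raise FormulaSyntaxError(
                f"unexpected character {m.group('bad')!r} at position {m.start('bad')}",
                position=m.start("bad"),
            )
        if m.group("band"):
            tokens.append(("band", int(m.group("band")[1:]), m.start("band")))
        elif m.group("number") is not None:
            tokens.append(("num", float(m.group(0)), m.start("number")))
        else:
            op = _OP_ALIASES.get(m.group("op"), m.group("op"))
            tokens.append(("op", op, m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser: standard precedence, left associativity."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise FormulaSyntaxError(
                f"unexpected {tok[1]!r} at position {tok[2]}", position=tok[2]
            )
        return node

    def expr(self):
        node = self.term()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "+-":
            self.next()
            node = (tok[1], node, self.term())
        return node

    def term(self):
        node = self.factor()
        while (tok := self.peek()) and tok[0] == "op" and tok[1] in "*/":
            self.next()
            node = (tok[1], node, self.factor())
        return node

    def factor(self):
        tok = self.peek()
        if tok and tok[0] == "op" and tok[1] in "+-":
            self.next()
            child = self.factor()
            return child if tok[1] == "+" else ("neg", child)
        return self.primary()

    def primary(self):
        tok = self.next()
        if tok is None:
            raise FormulaSyntaxError(
                f"unexpected end of expression in {self.text!r}",
                position=len(self.text),
            )
        kind, value, pos = tok
        if kind == "num":
            return ("num", value)
        if kind == "band":
            return ("R", value)
        if kind == "op" and value == "(":
            node = self.expr()
            closing = self.next()
            if closing is None or closing[0] != "op" or closing[1] != ")":
                raise FormulaSyntaxError(
                    f"unbalanced parenthesis opened at position {pos}", position=pos
                )
            return node
        raise FormulaSyntaxError(f"unexpected {value!r} at position {pos}", position=pos)


def _collect_bands(node, out: set[int]) -> None:
    op = node[0]
    if op == "R":
        out.add(node[1])
    elif op == "num":
        pass
    elif op == "neg":
        _collect_bands(node[1], out)
    else:
        _collect_bands(node[1], out)
        _collect_bands(node[2], out)


@dataclass(frozen=True)
class VegetationIndexDefinition:
    """A named band-math formula plus the wavelengths it requires."""

    name: str
    formula: str
    ast: tuple = field(repr=False, compare=False)
    required_wavelengths: frozenset[int] = field(default_factory=frozenset)
    scale_invariant: bool = False
    reference: str = ""


@dataclass
class IndexResult:
    """Per-sample values of one index; NaN marks a missing value."""

    index_name: str
    values: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.name = self.index_name


def parse_formula(
    text: str,
    name: str = "custom",
    reference: str = "user-defined",
    scale_invariant: bool = False,
) -> VegetationIndexDefinition:
    """Parse a band-math expression into an index definition.

    Bands outside the 400–1,000 nm working range trigger a warning (the
    definition is still accepted; evaluation simply reports missing values
    wherever the band is absent from a collection's grid).
    """
    if not text or not text.strip():
        raise FormulaSyntaxError("empty formula")
    ast = _Parser(text).parse()
    bands: set[int] = set()
    _collect_bands(ast, bands)
    lo, hi = VALID_BAND_RANGE_NM
    outside = sorted(b for b in bands if not lo <= b <= hi)
    if outside:
        import warnings

        warnings.warn(
            f"index {name!r} references wavelengths outside "
            f"{lo}–{hi} nm: {outside}",
            stacklevel=2,
        )
    return VegetationIndexDefinition(
        name=name,
        formula=text.strip(),
        ast=ast,
        required_wavelengths=frozenset(bands),
        scale_invariant=scale_invariant,
        reference=reference,
    )


# --------------------------------------------------------------------------
# Registry
# --------------------------------------------------------------------------

def _registry_path():
    return resources.files("proxispec.data") / "vegetation_indices.tsv"


def load_registry(path=None, extra: Iterable = ()) -> list[VegetationIndexDefinition]:
    """Load index definitions from the bundled (or a user) registry file.

    The registry is tab-delimited with columns
    ``name  formula  scale_invariant  reference`` and ``#`` comment lines.
    ``extra`` may list additional registry file paths appended after the
    bundled definitions; duplicate names are a load error.
    """
    if path is None:
        text = _registry_path().read_text()
        source = "bundled registry"
    else:
        with open(path) as fh:
            text = fh.read()
        source = str(path)
    defs = _parse_registry_text(text, source)
    names = {d.name for d in defs}
    for extra_path in extra:
        with open(extra_path) as fh:
            more = _parse_registry_text(fh.read(), str(extra_path))
        for d in more:
            if d.name in names:
                raise RegistryError(
                    f"{extra_path}: index {d.name!r} already defined"
                )
            names.add(d.name)
            defs.append(d)
    return defs


def _parse_registry_text(text: str, source: str) -> list[VegetationIndexDefinition]:
    defs: list[VegetationIndexDefinition] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise RegistryError(
                f"{source}:{lineno}: expected 4 tab-separated fields "
                f"(name, formula, scale_invariant, reference), got {len(parts)}"
            )
        name, formula, inv, reference = (p.strip() for p in parts)
        if name in seen:
            raise RegistryError(f"{source}:{lineno}: duplicate index name {name!r}")
        if inv not in ("y", "n"):
            raise RegistryError(
                f"{source}:{lineno}: scale_invariant must be 'y' or 'n', got {inv!r}"
            )
        seen.add(name)
        try:
            d = parse_formula(
                formula, name=name, reference=reference, scale_invariant=inv == "y"
            )
        except FormulaSyntaxError as exc:
            raise RegistryError(f"{source}:{lineno}: {exc}") from exc
        lo, hi = VALID_BAND_RANGE_NM
        bad = sorted(b for b in d.required_wavelengths if not lo <= b <= hi)
        if bad:
            raise RegistryError(
                f"{source}:{lineno}: index {name!r} uses bands outside "
                f"{lo}–{hi} nm: {bad}"
            )
        defs.append(d)
    return defs


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def _eval_ast(node, bands: dict[int, np.ndarray], n: int) -> np.ndarray:
    op = node[0]
    if op == "num":
        return np.full(n, node[1])
    if op == "R":
        return bands[node[1]]
    if op == "neg":
        return -_eval_ast(node[1], bands, n)
    left = _eval_ast(node[1], bands, n)
    right = _eval_ast(node[2], bands, n)
    if op == "+":
        return left + right
    if op == "-":
        return left - right
    if op == "*":
        return left * right
    # division: a zero denominator makes the sample's value missing
    with np.errstate(divide="ignore", invalid="ignore"):
        out = left / right
    out = np.where(right == 0, np.nan, out)
    return out


def evaluate_index(
    collection: SpectralCollection, definition: VegetationIndexDefinition
) -> IndexResult:
    """Evaluate one index on every sample of a collection.

    A sample's value is missing (NaN) when any required wavelength is absent
    from the grid, when any referenced band value is itself missing, or when
    a division by zero occurs.  Evaluation is total: no exceptions escape.
    """
    n = collection.n_samples
    band_values: dict[int, np.ndarray] = {}
    missing_band = False
    for wl in definition.required_wavelengths:
        col = collection.band(wl)
        if col is None:
            missing_band = True
            break
        band_values[wl] = col
    if missing_band:
        values = np.full(n, np.nan)
    else:
        values = _eval_ast(definition.ast, band_values, n)
        values = np.where(np.isfinite(values), values, np.nan)
    return IndexResult(
        definition.name, pd.Series(values, index=collection.sample_ids)
    )


def evaluate_all(
    collection: SpectralCollection,
    definitions: Sequence[VegetationIndexDefinition],
) -> pd.DataFrame:
    """Samples x indices value matrix; column order follows the registry."""
    if not definitions:
        raise ValueError("evaluate_all requires at least one definition")
    columns = {
        d.name: evaluate_index(collection, d).values for d in definitions
    }
    return pd.DataFrame(columns, index=collection.sample_ids)
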