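"""Categorical protein-expression overlay for pathway networks.

Protein expression in glioblastoma is compared against four healthy
cerebral-cortex contexts (endothelial cells, glial cells, neuronal cells,
neuropil).  Cortex levels are categorical (Not Detected < Low < Medium <
High, with N/A and Uncertain excluded from comparison); tumor levels are
per-category sample counts over a shared denominator (e.g. 8/12 samples
scored High).  The overlay

* parses the tab-separated expression table,
* summarises each protein's tumor profile by its modal category (ties
  broken toward the higher category — conservative when screening for
  over-expressed drug targets),
* flags each protein up/down/same per cortex context on the ordinal scale,
* paints a user-supplied pathway graph: in cortex mode each node carries
  four quarter colors (clockwise: endothelial, neuropil, neuronal,
  glial); in tumor mode each node carries pie fractions per category.

Color legend: olive = not available, deep sky blue = not detected,
green = low, medium orchid = medium, deep pink = high.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx

__all__ = [
    "ExpressionRecord",
    "parse_expression_table",
    "modal_tumor_category",
    "differential_flags",
    "annotate_network",
    "read_sif",
    "load_expression_fixture",
    "load_synthetic_network",
    "CELL_TYPES",
    "TUMOR_CATEGORIES",
    "CATEGORY_COLORS",
    "OverlayError",
    "ParseError",
]

CELL_TYPES = ("endothelial", "glial", "neuronal", "neuropil")
#: quarter painting order on the node circle (clockwise)
QUARTER_ORDER = ("endothelial", "neuropil", "neuronal", "glial")
TUMOR_CATEGORIES = ("Not Detected", "Low", "Medium", "High")
ORDINAL = {"Not Detected": 0, "Low": 1, "Medium": 2, "High": 3}
EXCLUDED = ("N/A", "Uncertain")

CATEGORY_COLORS = {
    "N/A": "olive",
    "Uncertain": "olive",
    "Not Detected": "deep sky blue",
    "Low": "green",
    "Medium": "medium orchid",
    "High": "deep pink",
}
NOT_AVAILABLE_COLOR = "olive"

_HEADER = (
    "Class", "Protein", "Endothelial cells", "Glial cells", "Neuronal cells",
    "Neuropil", "Not detected", "Low", "Medium", "High",
)


class OverlayError(ValueError):
    """Semantic error in overlay inputs (duplicate symbols, missing data)."""


class ParseError(OverlayError):
    """Malformed expression table."""


@dataclass(frozen=True)
class ExpressionRecord:
    """One expression-table row.

    ``cortex`` maps cell type to a category in
    {High, Medium, Low, Not Detected, N/A, Uncertain}.  ``tumor_counts``
    are per-category sample counts (Not Detected, Low, Medium, High) over
    denominator ``n``; both are None when the row carries no usable tumor
    data.
    """

    protein_class: str
    symbol: str
    cortex: dict[str, str]
    tumor_counts: tuple[int, int, int, int] | None
    n: int | None

    @property
    def has_tumor_data(self) -> bool:
        return self.tumor_counts is not None


def _parse_category(cell: str) -> str:
    cell = cell.strip()
    if cell == "?":
        return "Uncertain"
    if cell.upper().startswith("N/A") or cell == "":
        return "N/A"
    canonical = {c.lower(): c for c in ORDINAL}
    if cell.lower() not in canonical:
        raise ParseError(f"unknown expression category {cell!r}")
    return canonical[cell.lower()]


def _parse_count_cell(cell: str, lineno: int) -> tuple[int, int | None] | None:
    """Return (count, denominator) — denominator None for a bare count —
    or None for an N/A cell."""
    cell = cell.strip()
    if cell == "" or cell.upper().startswith("N/A"):
        return None
    if "/" in cell:
        parts = cell.split("/")
        try:
            a, b = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            raise ParseError(f"line {lineno}: malformed fraction {cell!r}") from None
        if len(parts) != 2 or a < 0 or b <= 0 or a > b:
            raise ParseError(f"line {lineno}: malformed fraction {cell!r}")
        return a, b
    try:
        count = int(cell)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed count {cell!r}") from None
    if count < 0:
        raise ParseError(f"line {lineno}: negative count {cell!r}")
    return count, None


def parse_expression_table(source: str | Path | io.TextIOBase) -> list[ExpressionRecord]:
    """Parse a TSV expression table into one record per protein row.

    Accepts a path, a TSV string, or an open text stream.  The class
    column is forward-filled (a blank class cell continues the previous
    protein class).  Fraction cells ``a/b`` give count ``a`` over
    denominator ``b``; bare ``0`` inherits the row's denominator; rows
    whose tumor cells are all N/A are flagged as carrying no tumor data.
    Mixed denominators within a row are an error naming the protein.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        p = Path(source) if not isinstance(source, Path) else source
        try:
            is_file = p.is_file()
        except OSError:  # e.g. embedded newlines in a TSV string
            is_file = False
        text = p.read_text() if is_file else str(source)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty expression table")
    header = tuple(c.strip() for c in lines[0].split("\t"))
    if tuple(h.lower() for h in header) != tuple(h.lower() for h in _HEADER):
        raise ParseError(
            f"unexpected header {header!r}; expected columns {_HEADER!r}"
        )

    records: list[ExpressionRecord] = []
    current_class = ""
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) != len(_HEADER):
            raise ParseError(
                f"line {lineno}: expected {len(_HEADER)} columns, got {len(cells)}"
            )
        if cells[0]:
            current_class = cells[0]
        symbol = cells[1]
        if not symbol:
            raise ParseError(f"line {lineno}: missing protein symbol")
        cortex = {
            ct: _parse_category(cells[2 + i]) for i, ct in enumerate(CELL_TYPES)
        }
        parsed = [_parse_count_cell(cells[6 + i], lineno) for i in range(4)]
        if all(p is None for p in parsed):
            counts, n = None, None
        else:
            denoms = {p[1] for p in parsed if p is not None and p[1] is not None}
            if len(denoms) > 1:
                raise ParseError(
                    f"inconsistent denominators {sorted(denoms)} for protein "
                    f"{symbol} (line {lineno})"
                )
            if not denoms:
                raise ParseError(
                    f"line {lineno}: no denominator given for protein {symbol}"
                )
            n = denoms.pop()
            counts = tuple(0 if p is None else p[0] for p in parsed)
            if sum(counts) != n:
                raise ParseError(
                    f"tumor counts {counts} for protein {symbol} sum to "
                    f"{sum(counts)}, not the denominator {n} (line {lineno})"
                )
        records.append(
            ExpressionRecord(
                protein_class=current_class, symbol=symbol, cortex=cortex,
                tumor_counts=counts, n=n,
            )
        )
    return records


def modal_tumor_category(record: ExpressionRecord) -> tuple[str, int, int]:
    """Most frequent tumor category as ``(category, count, denominator)``.

    Ties break toward the higher expression category (a documented,
    deliberately conservative convention for target screening).
    """
    if not record.has_tumor_data:
        raise OverlayError(f"protein {record.symbol} has no usable tumor data (N/A)")
    best = max(range(4), key=lambda i: (record.tumor_counts[i], i))
    return TUMOR_CATEGORIES[best], record.tumor_counts[best], record.n


def differential_flags(record: ExpressionRecord) -> dict[str, str]:
    """Per-cell-type flag in {up, down, same, incomparable}: modal tumor
    category versus the healthy-cortex category on the ordinal scale."""
    flags = {}
    if record.has_tumor_data:
        modal, _, _ = modal_tumor_category(record)
        tumor_rank = ORDINAL[modal]
    else:
        tumor_rank = None
    for ct in CELL_TYPES:
        cortex = record.cortex[ct]
        if tumor_rank is None or cortex in EXCLUDED:
            flags[ct] = "incomparable"
        else:
            diff = tumor_rank - ORDINAL[cortex]
            flags[ct] = "up" if diff > 0 else "down" if diff < 0 else "same"
    return flags


def _index_records(records: list[ExpressionRecord]) -> dict[str, ExpressionRecord]:
    index: dict[str, ExpressionRecord] = {}
    for rec in records:
        key = rec.symbol.lower()
        if key in index:
            raise OverlayError(f"duplicate protein symbol {rec.symbol!r} in records")
        index[key] = rec
    return index


def annotate_network(
    network: nx.Graph,
    records: list[ExpressionRecord],
    mode: str = "cortex",
) -> nx.Graph:
    """Return a copy of ``network`` with expression annotations on nodes.

    Nodes must carry a ``symbol`` attribute; matching against records is
    case-insensitive.  Cortex mode writes ``quarter_1_color`` …
    ``quarter_4_color`` (clockwise: endothelial, neuropil, neuronal,
    glial) plus per-cell-type colors; tumor mode writes ``pie_<category>``
    fractions summing to 1.  Unmatched nodes (and N/A categories) get the
    "not available" color.  Annotation is idempotent.
    """
    if mode not in ("cortex", "tumor"):
        raise OverlayError(f"mode must be 'cortex' or 'tumor', got {mode!r}")
    index = _index_records(records)
    annotated = network.copy()
    for node, data in annotated.nodes(data=True):
        if "symbol" not in data:
            raise OverlayError(f"node {node!r} has no 'symbol' attribute")
        rec = index.get(str(data["symbol"]).lower())
        data["expression_available"] = rec is not None
        if mode == "cortex":
            for i, ct in enumerate(QUARTER_ORDER, start=1):
                color = (
                    CATEGORY_COLORS[rec.cortex[ct]] if rec is not None
                    else NOT_AVAILABLE_COLOR
                )
                data[f"quarter_{i}_color"] = color
                data[f"color_{ct}"] = color
        else:
            if rec is not None and rec.has_tumor_data:
                for cat, count in zip(TUMOR_CATEGORIES, rec.tumor_counts):
                    key = f"pie_{cat.lower().replace(' ', '_')}"
                    data[key] = count / rec.n
                data["node_color"] = CATEGORY_COLORS[modal_tumor_category(rec)[0]]
            else:
                data["node_color"] = NOT_AVAILABLE_COLOR
                data["expression_available"] = False
    return annotated


def read_sif(path: str | Path) -> nx.DiGraph:
    """Read a simple-interaction-format edge list: each line
    ``source<TAB>relation<TAB>target [target ...]`` (whitespace-delimited
    also accepted).  Nodes get their name as ``symbol``."""
    graph = nx.DiGraph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 1:
            graph.add_node(parts[0], symbol=parts[0])
            continue
        if len(parts) < 3:
            raise ParseError(f"malformed SIF line: {line!r}")
        src, rel, *targets = parts
        graph.add_node(src, symbol=src)
        for tgt in targets:
            graph.add_node(tgt, symbol=tgt)
            graph.add_edge(src, tgt, relationship=rel)
    return graph


def _data_path(name: str):
    return resources.files("bbbsim.data").joinpath(name)


def load_expression_fixture() -> list[ExpressionRecord]:
    """The packaged cortex/tumor expression table."""
    return parse_expression_table(_data_path("cortex_tumor_expression.tsv").read_text())


def load_synthetic_network() -> nx.Graph:
    """The packaged synthetic demonstration pathway graph (its topology
    makes no biological claim; it exists to exercise annotation)."""
    with resources.as_file(_data_path("synthetic_pathway.graphml")) as p:
        return nx.read_graphml(p)
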