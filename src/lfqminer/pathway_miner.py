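"""Pathway gene-set mining: resolve a Reactome-style pathway to a gene set,
convert human symbols to mouse orthologs, and pull the matching proteins out
of the expression dataset.

Gene sets are read from GMT-style files so the library works offline;
Reactome pathway gene lists are human by default and need ortholog
conversion before matching mouse data.  Matching is case-insensitive and
ignores the ``.1``/``.2`` uniquification suffixes that duplicate symbols
carry in the dataset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .diffexpr import ContrastResult, results_wide_table
from .errors import FormatError, ValidationError
from .global_viz import zscore_rows
from .preprocess import ExpressionDataset

log = logging.getLogger(__name__)

REACTOME_ID_RE = re.compile(r"^R-[A-Z]{3}-[0-9]+$")
_SUFFIX_RE = re.compile(r"\.\d+$")


@dataclass
class GeneSet:
    """A named collection of gene symbols tagged with its species."""

    set_id: str
    name: str
    species: str  # "human" | "mouse"
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        if self.species not in ("human", "mouse"):
            raise ValidationError(f"unknown species tag {self.species!r}")
        if self.set_id.startswith("R-") and not REACTOME_ID_RE.match(self.set_id):
            raise ValidationError(f"malformed Reactome id {self.set_id!r}")


@dataclass
class MiningResult:
    """Rows of the dataset matching a gene set, plus the genes it lacked."""

    matched_ids: list[str]
    matched_matrix: pd.DataFrame  # log2 intensities of the matched rows
    not_detected: frozenset[str]  # gene-set members absent from the dataset
    zmatrix: pd.DataFrame = field(default_factory=pd.DataFrame)
    export: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_matched_genes(self) -> int:
        """Distinct gene-set members found (suffixed duplicates count once)."""
        return len({strip_suffix(i).casefold() for i in self.matched_ids})


def strip_suffix(identifier: str) -> str:
    """Remove a trailing ``.N`` uniquification suffix."""
    return _SUFFIX_RE.sub("", identifier)


def load_gene_sets(path: str) -> dict[str, GeneSet]:
    """Parse a GMT-style file: ``set_id TAB name TAB gene TAB gene ...``."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected set_id<TAB>name<TAB>genes..., "
                    f"got {len(parts)} fields"
                )
            set_id, name = parts[0].strip(), parts[1].strip()
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no genes")
            species = "human" if set_id.startswith("R-HSA") else "mouse"
            sets[set_id] = GeneSet(set_id=set_id, name=name, species=species, genes=genes)
    return sets


def to_mouse_symbols(
    gs: GeneSet, mapping: pd.DataFrame | None = None
) -> GeneSet:
    """Convert a human gene set to mouse symbols.

    With an ortholog table (columns human_symbol, mouse_symbol; one-to-many
    allowed, union taken) mapped symbols are replaced and unmapped ones fall
    through to the capitalization heuristic.  Without a table every symbol
    uses the heuristic: first character uppercase, remainder lowercase
    (CYP4A14 -> Cyp4a14) — adequate for most mouse/human symbol pairs but
    not true orthology.
    """
    if gs.species == "mouse":
        return gs
    lut: dict[str, set[str]] = {}
    if mapping is not None:
        for h, m in zip(mapping["human_symbol"], mapping["mouse_symbol"]):
            lut.setdefault(str(h).casefold(), set()).add(str(m))
    out: set[str] = set()
    for g in gs.genes:
        mapped = lut.get(g.casefold())
        if mapped:
            out |= mapped
        else:
            out.add(g[:1].upper() + g[1:].lower())
    return GeneSet(set_id=gs.set_id, name=gs.name, species="mouse", genes=frozenset(out))


def curated_pathways() -> dict[str, GeneSet]:
    """The built-in starter menu of metabolism pathways.

    Ships as a packaged GMT fixture whose gene lists are synthetic
    placeholders (plausible members, not an authoritative Reactome
    snapshot); supply your own GMT export for real analyses.
    """
    from importlib import resources

    ref = resources.files("lfqminer").joinpath("data/curated_pathways.synthetic.gmt")
    with resources.as_file(ref) as path:
        return load_gene_sets(str(path))


def load_ortholog_mapping(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"human_symbol", "mouse_symbol"}
    if not need <= set(df.columns):
        raise FormatError(f"ortholog table {path!r} needs columns {sorted(need)}")
    return df


def match_ids(dataset_ids: list[str], genes: frozenset[str]) -> tuple[list[str], frozenset[str]]:
    """Case- and suffix-insensitive matching of dataset row ids to set genes.

    Returns (matched dataset ids in dataset order, set genes not detected).
    Matched and not-detected partition the gene set exactly.
    """
    wanted = {g.casefold(): g for g in genes}
    matched: list[str] = []
    found: set[str] = set()
    for rid in dataset_ids:
        key = strip_suffix(rid).casefold()
        if key in wanted:
            matched.append(rid)
            found.add(wanted[key])
    return matched, frozenset(genes - found)


def extract_pathway(
    ds: ExpressionDataset,
    gs: GeneSet,
    results: list[ContrastResult] | None = None,
) -> MiningResult:
    """Extract the gene set's proteins from the dataset.

    The export table carries the log2 intensities, the matched set
    membership, and (when contrast results are supplied) every contrast's
    statistics.  An empty match is a warning, not an error.
    """
    if ds.stage != "imputed":
        raise ValidationError("mining requires an imputed dataset")
    matched, absent = match_ids(ds.ids, gs.genes)
    if not matched:
        log.warning("gene set %s matched no proteins in the dataset", gs.set_id)
        return MiningResult([], ds.matrix.iloc[0:0], absent)
    sub = ds.matrix.loc[matched]
    export = sub.copy()
    export.insert(0, "gene_set", gs.set_id)
    if results:
        export = export.join(results_wide_table(results).loc[matched])
    return MiningResult(
        matched_ids=matched,
        matched_matrix=sub,
        not_detected=absent,
        zmatrix=zscore_rows(sub),
        export=export,
    )


def write_mining_export(res: MiningResult, path: str) -> None:
    res.export.to_csv(path, sep="\t", float_format="%.6f")
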