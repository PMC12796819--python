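"""Reading MaxQuant ``proteinGroups.txt`` and the sample-conditions design file.

MaxQuant writes one row per protein group with ``LFQ intensity <label>``
columns (one per sample) and ``+``-coded flag columns marking reverse-decoy
hits, potential contaminants and site-only identifications.  An LFQ value of
0 means the protein was not quantified in that sample and is stored here as
missing, the convention shared by Perseus and DEP.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "
FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}
DESIGN_HEADER = ["label", "condition", "replicate", "order"]


@dataclass
class ProteinGroupsTable:
    """Parsed protein-group matrix.

    ``lfq`` is a proteins x samples DataFrame of raw intensities with NaN for
    "not quantified"; ``flags`` holds the three boolean hygiene columns; and
    ``unique_id`` is a display identifier derived from the gene symbol
    (first accession as fallback, ``.1``/``.2`` suffixes for duplicates).
    """

    protein_ids: list[str]
    majority_protein_ids: list[str]
    gene_names: list[str]
    unique_id: list[str]
    flags: pd.DataFrame
    lfq: pd.DataFrame
    sample_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_labels:
            self.sample_labels = list(self.lfq.columns)
        if len(set(self.sample_labels)) != len(self.sample_labels):
            raise ValidationError("duplicate sample labels in LFQ columns")
        if len(set(self.unique_id)) != len(self.unique_id):
            raise ValidationError("unique_id values are not unique")

    def __len__(self) -> int:
        return len(self.unique_id)

    def subset(self, keep: list[bool]) -> "ProteinGroupsTable":
        """Row subset preserving column order and identifiers."""
        idx = [i for i, k in enumerate(keep) if k]
        return ProteinGroupsTable(
            protein_ids=[self.protein_ids[i] for i in idx],
            majority_protein_ids=[self.majority_protein_ids[i] for i in idx],
            gene_names=[self.gene_names[i] for i in idx],
            unique_id=[self.unique_id[i] for i in idx],
            flags=self.flags.iloc[idx].reset_index(drop=True),
            lfq=self.lfq.iloc[idx].reset_index(drop=True),
            sample_labels=list(self.sample_labels),
        )


@dataclass
class ExperimentDesign:
    """One row per sample: label, condition, replicate and (unused) order."""

    table: pd.DataFrame  # columns: label, condition, replicate, order

    def __post_init__(self) -> None:
        t = self.table
        dup = t["label"][t["label"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate sample labels in design: {dup}")
        if t["condition"].nunique() < 2:
            raise ValidationError(
                "design must contain at least 2 conditions, got "
                f"{sorted(t['condition'].unique())}"
            )
        counts = t.groupby("condition").size()
        thin = counts[counts < 2]
        if len(thin):
            raise ValidationError(
                f"every condition needs >= 2 replicates; offending: {dict(thin)}"
            )
        pairs = t[["condition", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            bad = pairs[pairs.duplicated()].tolist()
            raise ValidationError(f"duplicate (condition, replicate) pairs: {bad}")

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def conditions(self) -> list[str]:
        """Condition names in order of first appearance."""
        return list(dict.fromkeys(self.table["condition"]))

    def replicate_counts(self) -> dict[str, int]:
        return self.table.groupby("condition").size().to_dict()

    def samples_of(self, condition: str) -> list[str]:
        t = self.table
        return t.loc[t["condition"] == condition, "label"].tolist()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentDesign):
            return NotImplemented
        return self.table.reset_index(drop=True).equals(
            other.table.reset_index(drop=True)
        )


def uniquify_ids(gene_names: list[str], fallback_ids: list[str]) -> list[str]:
    """Turn raw gene-symbol strings into unique display identifiers.

    Empty symbols fall back to the first accession; semicolon-delimited
    symbols keep the first token; duplicates get ``.1``, ``.2``, ... suffixes
    in row order with the first occurrence left bare.  Total function: every
    input produces an identifier.
    """
    if len(gene_names) != len(fallback_ids):
        raise ValidationError("gene_names and fallback_ids differ in length")
    base: list[str] = []
    for name, fb in zip(gene_names, fallback_ids):
        name = (name or "").strip()
        token = name.split(";")[0].strip() if name else ""
        if not token:
            token = str(fb).split(";")[0].strip()
        base.append(token)
    seen: dict[str, int] = {}
    out: list[str] = []
    existing = set(base)
    for token in base:
        n = seen.get(token, 0)
        if n == 0:
            cand = token
        else:
            cand = f"{token}.{n}"
            # avoid colliding with a literal "X.1" already present in input
            while cand in existing or cand in out:
                n += 1
                cand = f"{token}.{n}"
        seen[token] = n + 1
        out.append(cand)
    return out


def parse_protein_groups(path: str) -> ProteinGroupsTable:
    """Parse a MaxQuant ``proteinGroups.txt``.

    Every column whose header starts with ``"LFQ intensity "`` becomes a
    sample column (label = header remainder).  Flag columns map ``"+"`` to
    True; a missing flag column is treated as all-False with a warning.
    Intensity 0 is stored as missing (NaN).  No rows are ever dropped here.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read protein groups file {path!r}: {exc}") from exc
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(
            f"{path!r} has no 'LFQ intensity <label>' columns; "
            "is this a MaxQuant proteinGroups.txt with LFQ enabled?"
        )
    labels = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    lfq = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    lfq.columns = labels
    if (lfq < 0).any().any():
        raise FormatError(f"negative LFQ intensity found in {path!r}")
    lfq = lfq.mask(lfq == 0)  # 0 == not quantified

    flags = pd.DataFrame(index=df.index)
    for key, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[key] = df[col].str.strip() == "+"
        else:
            log.warning("flag column %r absent in %s; assuming all-false", col, path)
            flags[key] = False

    def _col(name: str) -> list[str]:
        return df[name].tolist() if name in df.columns else [""] * len(df)

    protein_ids = _col("Protein IDs")
    majority = _col("Majority protein IDs")
    genes = _col("Gene names")
    unique = uniquify_ids(genes, protein_ids)
    return ProteinGroupsTable(
        protein_ids=protein_ids,
        majority_protein_ids=majority,
        gene_names=genes,
        unique_id=unique,
        flags=flags.reset_index(drop=True),
        lfq=lfq.reset_index(drop=True),
        sample_labels=labels,
    )


def make_design_template(table: ProteinGroupsTable) -> str:
    """Blank tab-delimited design skeleton, one row per sample label."""
    lines = ["\t".join(DESIGN_HEADER)]
    lines += [f"{label}\t\t\t" for label in table.sample_labels]
    return "\n".join(lines) + "\n"


def write_design(design: ExperimentDesign, path: str) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def parse_design(
    path_or_buf: str | io.StringIO, table: ProteinGroupsTable | None = None
) -> ExperimentDesign:
    """Parse and validate a completed design file.

    `order` is accepted but optional (filled with row order when absent); it
    is carried through untouched and never used by the analysis.  When the
    protein-groups table is given, the label sets must match exactly.
    """
    try:
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read design file: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("label", "condition", "replicate") if c not in df.columns]
    if missing:
        raise FormatError(f"design file missing required columns: {missing}")
    if "order" not in df.columns:
        df["order"] = [str(i + 1) for i in range(len(df))]
    df = df[DESIGN_HEADER].copy()
    df["order"] = df["order"].replace("", None)
    df["order"] = df["order"].fillna(pd.Series(range(1, len(df) + 1), index=df.index).astype(str))
    blank = df[df["condition"].str.strip() == ""]
    if len(blank):
        raise ValidationError(
            f"rows with empty condition: labels {blank['label'].tolist()}"
        )
    for col in ("replicate", "order"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            raise ValidationError(f"non-integer {col} value in design: {exc}") from exc
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive")
    design = ExperimentDesign(df.reset_index(drop=True))
    if table is not None:
        want, got = set(table.sample_labels), set(design.labels)
        if want != got:
            raise ValidationError(
                "design labels do not match data sample labels; "
                f"missing from design: {sorted(want - got)}, "
                f"unknown in design: {sorted(got - want)}"
            )
    return design
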