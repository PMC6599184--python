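"""Readers, writers and validated containers for every external table.

All tabular formats are plain TSV (UTF-8, tab-separated, no quoting, first
column = row identifier, header row required); sequences travel as FASTA.
Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A file or string violates the expected format."""


class DataError(ValueError):
    """A well-formed file carries invalid values."""


# ---------------------------------------------------------------------------
# Lineage
# ---------------------------------------------------------------------------

_RANK_PREFIXES = {
    "p": "phylum",
    "c": "class_",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_RANK_ORDER = ("phylum", "class_", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """A Greengenes-style taxonomic lineage.

    Parsed from semicolon-delimited rank-prefixed tokens such as
    ``p_Bacteroidetes;c_Bacteroidia;o_Bacteroidales;f_Prevotellaceae;g_Prevotella``.
    An empty token after a prefix (``f_``) means the rank is unassigned.
    ``source_string`` preserves the input verbatim so lineages round-trip.
    """

    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    source_string: str = ""

    def to_string(self) -> str:
        return self.source_string

    def rank(self, name: str) -> str | None:
        return getattr(self, name)

    @property
    def deepest_rank(self) -> str | None:
        """Name of the deepest assigned rank, or None if fully unassigned."""
        for r in reversed(_RANK_ORDER):
            if getattr(self, r) is not None:
                return r
        return None

    def genus_key(self) -> str:
        """Canonical genus-level grouping key.

        OTUs are pooled by their (family, genus) assignment; lineages with an
        unassigned genus fall back to the full truncated lineage so distinct
        unresolved groups are not merged (mirrors genus-level collapse of an
        OTU table where ``f_;g_`` strings stay separate per parent clade).
        """
        parts = []
        for prefix, attr in zip("pcofg", _RANK_ORDER[:5]):
            val = getattr(self, attr)
            parts.append(f"{prefix}_{val if val is not None else ''}")
        return ";".join(parts)


def parse_lineage(text: str) -> Lineage:
    """Parse a rank-prefixed lineage string.

    An empty string yields a lineage with all ranks absent. Unknown rank
    prefixes raise :class:`FormatError` naming the offending token.
    """
    ranks: dict[str, str | None] = {}
    stripped = text.strip()
    if stripped:
        for token in stripped.split(";"):
            token = token.strip()
            m = re.fullmatch(r"([A-Za-z])_(.*)", token)
            if m is None or m.group(1).lower() not in _RANK_PREFIXES:
                raise FormatError(
                    f"unrecognized lineage token {token!r} in {text!r}"
                )
            attr = _RANK_PREFIXES[m.group(1).lower()]
            name = m.group(2).strip()
            ranks[attr] = name if name else None
    return Lineage(source_string=text, **ranks)


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Integer OTU count matrix (samples x OTUs) with per-OTU lineages."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # (n_samples, n_otus), non-negative integers
    lineages: list[Lineage]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise DataError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(self.lineages) != len(self.otu_ids):
            raise DataError("one lineage required per OTU")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise DataError("duplicate OTU ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise DataError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise DataError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def drop_singletons(self) -> "OtuTable":
        """Remove OTUs whose total count across all samples is <= 1."""
        keep = self.counts.sum(axis=0) >= 2
        return OtuTable(
            sample_ids=list(self.sample_ids),
            otu_ids=[o for o, k in zip(self.otu_ids, keep) if k],
            counts=self.counts[:, keep],
            lineages=[l for l, k in zip(self.lineages, keep) if k],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.otu_ids
        )


def read_otu_table(
    counts_path: str | Path,
    lineage_path: str | Path,
    drop_singletons: bool = False,
) -> OtuTable:
    """Read an OTU table (rows = OTUs, columns = samples) plus its lineage map.

    With ``drop_singletons`` set, OTUs totalling <= 1 read across all samples
    are removed; column order is otherwise preserved.
    """
    df = _read_tsv(counts_path)
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    counts = np.empty((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for j, otu in enumerate(otu_ids):
        for i, samp in enumerate(sample_ids):
            val = df.iloc[j, i]
            try:
                f = float(val)
            except (TypeError, ValueError):
                f = np.nan
            if not np.isfinite(f) or f != int(f) or f < 0:
                raise DataError(
                    f"non-integer or negative count {val!r} at OTU "
                    f"{otu!r}, sample {samp!r}"
                )
            counts[i, j] = int(f)

    lin_df = _read_tsv(lineage_path)
    lin_map = {str(k): str(v) if not pd.isna(v) else "" for k, v in
               lin_df.iloc[:, 0].items()}
    lineages = []
    for otu in otu_ids:
        if otu not in lin_map:
            raise DataError(f"OTU {otu!r} has no lineage entry")
        lineages.append(parse_lineage(lin_map[otu]))

    table = OtuTable(sample_ids, otu_ids, counts, lineages)
    if drop_singletons:
        table = table.drop_singletons()
    return table


def write_otu_table(
    table: OtuTable, counts_path: str | Path, lineage_path: str | Path
) -> None:
    """Write the canonical TSV pair (counts: rows = OTUs; lineage map)."""
    df = pd.DataFrame(
        table.counts.T, index=table.otu_ids, columns=table.sample_ids
    )
    df.index.name = "otu_id"
    df.to_csv(counts_path, sep="\t")
    lin = pd.DataFrame(
        {"lineage": [l.to_string() for l in table.lineages]},
        index=pd.Index(table.otu_ids, name="otu_id"),
    )
    lin.to_csv(lineage_path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

TREATMENTS = ("CON", "AMP+NEO", "ERY")
TIMEPOINTS = ("pre", "post")
DEFAULT_STRAINS = ("BALB/c", "C57BL/6")


@dataclass(frozen=True)
class SampleMeta:
    """One 16S sample: which mouse, arm and timepoint it came from."""

    sample_id: str
    mouse_id: str
    strain: str
    treatment: str
    timepoint: str
    cage_id: str = ""


def validate_meta(
    meta: Sequence[SampleMeta],
    strains: tuple[str, str] = DEFAULT_STRAINS,
) -> None:
    """Check the repeated-measures design invariants.

    Each mouse contributes at most one sample per timepoint, and strain and
    treatment never change within a mouse.
    """
    seen: dict[tuple[str, str], str] = {}
    mouse_attrs: dict[str, tuple[str, str]] = {}
    for m in meta:
        if m.strain not in strains:
            raise DataError(f"unknown strain {m.strain!r} for {m.sample_id!r}")
        if m.treatment not in TREATMENTS:
            raise DataError(
                f"unknown treatment {m.treatment!r} for {m.sample_id!r}"
            )
        if m.timepoint not in TIMEPOINTS:
            raise DataError(
                f"unknown timepoint {m.timepoint!r} for {m.sample_id!r}"
            )
        key = (m.mouse_id, m.timepoint)
        if key in seen:
            raise DataError(
                f"mouse {m.mouse_id!r} has two samples at {m.timepoint!r}"
            )
        seen[key] = m.sample_id
        attrs = (m.strain, m.treatment)
        if mouse_attrs.setdefault(m.mouse_id, attrs) != attrs:
            raise DataError(
                f"mouse {m.mouse_id!r} changes strain/treatment across samples"
            )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path)
    required = {"mouse_id", "strain", "treatment", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    meta = [
        SampleMeta(
            sample_id=str(idx),
            mouse_id=str(row["mouse_id"]),
            strain=str(row["strain"]),
            treatment=str(row["treatment"]),
            timepoint=str(row["timepoint"]),
            cage_id=str(row["cage_id"]) if "cage_id" in df.columns else "",
        )
        for idx, row in df.iterrows()
    ]
    validate_meta(meta, strains=tuple(sorted({m.strain for m in meta}))
                  if {m.strain for m in meta} - set(DEFAULT_STRAINS)
                  else DEFAULT_STRAINS)
    return meta


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mouse_id": [m.mouse_id for m in meta],
            "strain": [m.strain for m in meta],
            "treatment": [m.treatment for m in meta],
            "timepoint": [m.timepoint for m in meta],
            "cage_id": [m.cage_id for m in meta],
        },
        index=pd.Index([m.sample_id for m in meta], name="sample_id"),
    )
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# miRNA probe counts
# ---------------------------------------------------------------------------

PROBE_CLASSES = ("endogenous", "negative", "positive", "ligation")


@dataclass
class MirnaCounts:
    """NanoString-style probe x sample count matrix with probe classes.

    At least two negative and two positive control probes are required
    (the background threshold needs a spread estimate; normalization needs a
    positive-control sum per lane).
    """

    probe_ids: list[str]
    probe_class: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_probes, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataError("count matrix shape does not match probe/sample ids")
        if len(self.probe_class) != len(self.probe_ids):
            raise DataError("one class label required per probe")
        bad = set(self.probe_class) - set(PROBE_CLASSES)
        if bad:
            raise DataError(f"unknown probe classes: {sorted(bad)}")
        if (self.counts < 0).any():
            raise DataError("negative probe counts")
        cls = np.asarray(self.probe_class)
        if (cls == "negative").sum() < 2:
            raise DataError(">= 2 negative control probes required")
        if (cls == "positive").sum() < 2:
            raise DataError(">= 2 positive control probes required")

    def class_mask(self, name: str) -> np.ndarray:
        return np.asarray(self.probe_class) == name

    @property
    def endogenous_ids(self) -> list[str]:
        return [p for p, c in zip(self.probe_ids, self.probe_class)
                if c == "endogenous"]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.probe_ids,
                          columns=self.sample_ids)
        df.insert(0, "probe_class", self.probe_class)
        return df


def read_mirna_counts(path: str | Path) -> MirnaCounts:
    df = _read_tsv(path)
    if "probe_class" not in df.columns:
        raise FormatError("miRNA count table needs a probe_class column")
    classes = [str(c) for c in df["probe_class"]]
    mat = df.drop(columns="probe_class")
    return MirnaCounts(
        probe_ids=[str(i) for i in df.index],
        probe_class=classes,
        sample_ids=[str(c) for c in mat.columns],
        counts=mat.to_numpy(dtype=float),
    )


def write_mirna_counts(mc: MirnaCounts, path: str | Path) -> None:
    df = mc.to_dataframe()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------

_DNA_OK = re.compile(r"[ACGT]*\Z")


@dataclass
class GeneCatalog:
    """Bacterial gene sequences with optional lineage and annotation ids.

    Emulates a gut microbial gene catalog: sequences are uppercase DNA and a
    fraction of genes may lack taxonomic classification (absent lineage).
    """

    gene_ids: list[str]
    sequences: dict[str, str]
    lineages: dict[str, Lineage] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        for gid in self.gene_ids:
            seq = self.sequences.get(gid, "")
            if not seq:
                raise DataError(f"gene {gid!r} has an empty sequence")
            if not _DNA_OK.fullmatch(seq):
                raise DataError(f"gene {gid!r} has non-ACGT characters")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def total_length(self) -> int:
        return sum(len(self.sequences[g]) for g in self.gene_ids)

    def lineage_of(self, gene_id: str) -> Lineage | None:
        return self.lineages.get(gene_id)


def normalize_dna(seq: str, context: str = "sequence") -> str:
    """Uppercase and map RNA U to T; reject anything outside ACGT."""
    s = seq.upper().replace("U", "T")
    if not _DNA_OK.fullmatch(s):
        bad = sorted(set(s) - set("ACGT"))
        raise DataError(f"{context}: invalid characters {bad}")
    return s


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into id -> normalized DNA, rejecting duplicate ids."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DataError(f"duplicate record id {rec.id!r}")
        out[rec.id] = normalize_dna(str(rec.seq), context=f"record {rec.id!r}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_gene_catalog(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> GeneCatalog:
    """Read a gene catalog FASTA plus an optional annotation TSV.

    The annotation file maps gene_id to a lineage string (may be blank: the
    catalog's unclassified fraction) and an annotation id ("NA" means none).
    """
    seqs = read_fasta(fasta_path)
    gene_ids = list(seqs)
    lineages: dict[str, Lineage] = {}
    annotations: dict[str, str] = {}
    if annotation_path is not None:
        ann = _read_tsv(annotation_path)
        for gid, row in ann.iterrows():
            gid = str(gid)
            lin_str = row.get("lineage")
            if lin_str is not None and not pd.isna(lin_str) and str(lin_str):
                lineages[gid] = parse_lineage(str(lin_str))
            a = row.get("annotation_id")
            if a is not None and not pd.isna(a) and str(a) not in ("", "NA"):
                annotations[gid] = str(a)
    return GeneCatalog(gene_ids, seqs, lineages, annotations)


def write_gene_catalog(
    cat: GeneCatalog, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    write_fasta({g: cat.sequences[g] for g in cat.gene_ids}, fasta_path)
    df = pd.DataFrame(
        {
            "lineage": [
                cat.lineages[g].to_string() if g in cat.lineages else ""
                for g in cat.gene_ids
            ],
            "annotation_id": [
                cat.annotations.get(g, "NA") for g in cat.gene_ids
            ],
        },
        index=pd.Index(cat.gene_ids, name="gene_id"),
    )
    df.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise FormatError(f"cannot read TSV {path}: {exc}") from exc


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a numeric TSV matrix (rows x columns, first column = row id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
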