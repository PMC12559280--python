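"""Readers and writers for the external formats the pipeline touches.

Methylomes arrive as per-cytosine count tables (Bismark-style cytosine
reports or bedGraph-like level tables), pedigrees as Newick strings or
edge-list TSVs, ring widths as CSV, and every intermediate product (state
matrices, divergence tables, fit reports) round-trips through deterministic
TSV.  All coordinates are 1-based closed, matching GFF3 and the Bismark
dialects.  Parsers never silently drop records: every input line is either
accepted or rejected with its line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree_growth import LineageTree

__all__ = [
    "MethylomeFormatError",
    "MethylomeValidationError",
    "ParseReport",
    "read_methylome",
    "write_methylome",
    "merge_cg_strands",
    "read_tree",
    "read_ring_series",
    "read_gene_models",
    "GeneModel",
    "write_state_matrix",
    "read_state_matrix",
    "write_divergence_table",
    "read_divergence_table",
    "write_fit_report",
]

METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]
CONTEXTS = ("CG", "CHG", "CHH")
_FLOAT_FMT = "%.10g"


class MethylomeFormatError(ValueError):
    """File does not look like any supported methylome dialect."""


class MethylomeValidationError(ValueError):
    """Records violate methylome invariants (with offending line numbers)."""


@dataclass
class ParseReport:
    n_lines: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class GeneModel:
    """A gene as sorted, non-overlapping exon intervals (1-based closed)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


def read_methylome(
    path: str | Path,
    contexts: tuple[str, ...] | None = None,
    errors: str = "raise",
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a per-cytosine methylation count table.

    Two headered dialects are auto-detected: a counts dialect
    (``count_methylated``/``count_total``) and a bedGraph-like level dialect
    (``level``/``count_total``, level in [0,1]).  Headerless 7-column Bismark
    cytosine reports (chrom pos strand meth unmeth context tri) are also
    accepted.  Returns the records sorted by (chrom, pos) plus a
    :class:`ParseReport` accounting for every input line.

    ``errors='collect'`` records malformed lines in the report instead of
    raising.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MethylomeFormatError(f"{path}: empty file")

    header = lines[0].rstrip("\n").split("\t")
    report = ParseReport(n_lines=len(lines))
    rows: list[tuple] = []

    def fail(lineno: int, msg: str) -> None:
        if errors == "raise":
            raise MethylomeValidationError(f"{path}:{lineno}: {msg}")
        report.rejected.append((lineno, msg))

    if {"chrom", "pos", "strand", "context"} <= set(header):
        if "count_methylated" in header and "count_total" in header:
            dialect = "counts"
        elif "level" in header and "count_total" in header:
            dialect = "level"
        else:
            raise MethylomeFormatError(
                f"{path}: header lacks count_methylated/count_total or level/count_total"
            )
        idx = {name: header.index(name) for name in header}
        body_start = 1
        report.n_lines -= 1  # header is not a record
    elif len(header) == 7 and header[1].isdigit():
        dialect = "bismark"
        body_start = 0
    else:
        raise MethylomeFormatError(
            f"{path}: unrecognised methylome dialect (header {header[:7]!r})"
        )

    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            report.n_lines -= 1
            continue
        parts = line.split("\t")
        try:
            if dialect == "bismark":
                chrom, pos, strand, meth, unmeth, context = (
                    parts[0], int(parts[1]), parts[2], int(parts[3]),
                    int(parts[4]), parts[5],
                )
                total = meth + unmeth
            else:
                chrom = parts[idx["chrom"]]
                pos = int(parts[idx["pos"]])
                strand = parts[idx["strand"]]
                context = parts[idx["context"]]
                total = int(parts[idx["count_total"]])
                if dialect == "counts":
                    meth = int(parts[idx["count_methylated"]])
                else:
                    level = float(parts[idx["level"]])
                    if not 0.0 <= level <= 1.0:
                        fail(lineno, f"level {level} outside [0,1]")
                        continue
                    meth = int(round(level * total))
        except (IndexError, ValueError) as exc:
            fail(lineno, f"malformed line: {exc}")
            continue
        if pos < 1:
            fail(lineno, f"position {pos} < 1")
            continue
        if strand not in ("+", "-"):
            fail(lineno, f"strand {strand!r} not +/-")
            continue
        if context not in CONTEXTS:
            fail(lineno, f"context {context!r} not in {CONTEXTS}")
            continue
        if meth < 0 or total < 0 or meth > total:
            fail(lineno, f"count_methylated={meth} > count_total={total}")
            continue
        rows.append((chrom, pos, strand, context, meth, total))

    df = pd.DataFrame(rows, columns=METHYLOME_COLUMNS)
    if contexts is not None:
        df = df[df["context"].isin(contexts)]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    report.n_accepted = len(rows)
    return df, report


def write_methylome(methylome: pd.DataFrame, path: str | Path) -> None:
    methylome[METHYLOME_COLUMNS].to_csv(path, sep="\t", index=False)


def merge_cg_strands(methylome: pd.DataFrame) -> pd.DataFrame:
    """Pool symmetric CG positions: the minus-strand cytosine of a CG
    dinucleotide (position p) is merged into its plus-strand partner (p-1).
    Non-CG records pass through untouched."""
    cg = methylome[methylome["context"] == "CG"].copy()
    rest = methylome[methylome["context"] != "CG"]
    cg["pair_pos"] = np.where(cg["strand"] == "-", cg["pos"] - 1, cg["pos"])
    merged = (
        cg.groupby(["chrom", "pair_pos"], as_index=False)
        .agg(count_methylated=("count_methylated", "sum"), count_total=("count_total", "sum"))
        .rename(columns={"pair_pos": "pos"})
    )
    merged["strand"] = "+"
    merged["context"] = "CG"
    out = pd.concat([merged[METHYLOME_COLUMNS], rest], ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_tree(path: str | Path) -> LineageTree:
    """Read a dated pedigree from Newick (branch lengths in years) or from an
    edge-list TSV with columns parent/child/length_years."""
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith("("):
        return LineageTree.from_newick(text)
    df = pd.read_csv(path, sep="\t")
    required = {"parent", "child", "length_years"}
    if not required <= set(df.columns):
        raise MethylomeFormatError(
            f"{path}: edge list needs columns {sorted(required)}, got {list(df.columns)}"
        )
    edges = [
        (str(r.parent), str(r.child), float(r.length_years)) for r in df.itertuples()
    ]
    return LineageTree.from_edges(edges)


def read_ring_series(path: str | Path) -> pd.DataFrame:
    """Ring-width CSV with columns year, width_mm and optionally direction."""
    df = pd.read_csv(path)
    if not {"year", "width_mm"} <= set(df.columns):
        raise MethylomeFormatError(f"{path}: ring CSV needs year and width_mm columns")
    if (df["width_mm"] < 0).any():
        raise MethylomeValidationError(f"{path}: negative ring widths")
    groups = df.groupby("direction") if "direction" in df.columns else [(None, df)]
    for _, grp in groups:
        years = np.sort(grp["year"].to_numpy())
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise MethylomeValidationError(f"{path}: years not contiguous")
    return df


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models (exon structure) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = [
            (exon.start, exon.end)
            for exon in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exons))
    return genes


# -- tabular intermediates ------------------------------------------------

def write_state_matrix(calls_by_sample: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Wide TSV: one row per unit, a state and posteriorMax column per sample.

    Every sample must be called on the same unit universe.
    """
    samples = sorted(calls_by_sample)
    base = calls_by_sample[samples[0]]
    unit_cols = [c for c in ("chrom", "pos", "start", "end", "context") if c in base.columns]
    out = base[unit_cols].copy()
    for sample in samples:
        calls = calls_by_sample[sample]
        if len(calls) != len(base):
            raise ValueError(f"sample {sample!r} called on a different unit universe")
        out[f"state_{sample}"] = calls["state"].to_numpy()
        out[f"posterior_max_{sample}"] = calls["posterior_max"].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_state_matrix(path: str | Path) -> dict[str, pd.DataFrame]:
    wide = pd.read_csv(path, sep="\t")
    unit_cols = [c for c in ("chrom", "pos", "start", "end", "context") if c in wide.columns]
    samples = [c[len("state_"):] for c in wide.columns if c.startswith("state_")]
    out = {}
    for sample in samples:
        df = wide[unit_cols].copy()
        df["state"] = wide[f"state_{sample}"]
        df["posterior_max"] = wide[f"posterior_max_{sample}"]
        out[sample] = df
    return out


DIVERGENCE_COLUMNS = ["sample_i", "sample_j", "context", "D", "n", "delta_t"]


def write_divergence_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DIVERGENCE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_divergence_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fit_report(fit, path: str | Path) -> None:
    """Flat key\\tvalue TSV of a neutral-model fit (parameters, SEs, diagnostics)."""
    rows = [
        ("alpha", fit.params.alpha), ("beta", fit.params.beta),
        ("c", fit.params.c), ("p0", fit.params.p0),
        ("gamma", fit.params.gamma), ("pi", fit.params.pi),
        ("se_alpha", fit.se_alpha), ("se_beta", fit.se_beta), ("se_c", fit.se_c),
        ("rss", fit.rss), ("n_pairs", fit.n_pairs),
        ("converged", int(fit.converged)), ("n_iterations", fit.n_iterations),
        ("se_reliable", int(fit.se_reliable)),
    ]
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in rows:
            fh.write(f"{key}\t{value:.10g}\n" if isinstance(value, float)
                     else f"{key}\t{value}\n")
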