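"""Readers and writers for every tabular format the pipeline touches.

All inputs are plain TSV/GMT text: a GISTIC2-coded gene x patient copy-number
matrix (cBioPortal export layout), a gene locus table (3-column TSV or BED),
pathway annotations in GMT, and a pair of GARP essentiality tables (scores and
cell-line mutation status).  Parsing is strict: values outside the declared
domains raise :class:`FormatError` naming the offending coordinates, and every
record that is dropped or modified on load is counted in a
:class:`LoadReport` attached to the returned object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GISTIC_VALUES = frozenset({-2, -1, 0, 1, 2})
STATUS_CODES = frozenset({"WT", "HOMDEL", "SOMATIC_MUT"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class LoadReport:
    """Counts of records dropped or modified while loading a file."""

    skipped_lines: int = 0
    dropped_records: int = 0
    messages: list[str] = field(default_factory=list)

    def note(self, message: str, *, skipped: int = 0, dropped: int = 0) -> None:
        self.skipped_lines += skipped
        self.dropped_records += dropped
        self.messages.append(message)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# GISTIC copy-number matrix
# ---------------------------------------------------------------------------

@dataclass
class GisticTable:
    """Discrete GISTIC2 scores (gene x patient), values in {-2,-1,0,1,2}.

    A score of -2 marks a homozygous (deep) deletion, -1 a hemizygous
    deletion, 0 diploid, +1/+2 weak/strong amplification.
    """

    gene_ids: list[str]
    patient_ids: list[str]
    scores: np.ndarray
    report: LoadReport = field(default_factory=LoadReport, compare=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        if self.scores.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise FormatError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.patient_ids)} patients"
            )
        _check_unique(self.gene_ids, "gene symbol")
        _check_unique(self.patient_ids, "sample ID")
        bad = ~np.isin(self.scores, list(GISTIC_VALUES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"GISTIC score {self.scores[i, j]} outside {{-2..2}} at "
                f"gene {self.gene_ids[i]!r}, sample {self.patient_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def read_gistic_matrix(path: str | Path, duplicate_policy: str = "error") -> GisticTable:
    """Read a cBioPortal-style GISTIC TSV (genes in rows, header of sample IDs).

    An ``Entrez_Gene_Id`` second column, if present, is dropped.
    ``duplicate_policy`` is ``"error"`` (default) or ``"first"`` (keep the
    first occurrence of a duplicated gene row, counted in the load report).
    """
    path = Path(path)
    report = LoadReport()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected tab-separated header with sample IDs")
    samples = header[1:]
    drop_entrez = bool(samples) and samples[0] == "Entrez_Gene_Id"
    if drop_entrez:
        samples = samples[1:]
        report.note("dropped Entrez_Gene_Id column")
    _check_unique(samples, "sample ID")

    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     keep_default_na=False)
    if drop_entrez:
        df = df.iloc[:, 1:]
    df.columns = samples

    genes = [str(g) for g in df.index]
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        if duplicate_policy == "error":
            raise FormatError(f"{path}: duplicate gene row {dup!r}")
        if duplicate_policy != "first":
            raise FormatError(f"unknown duplicate_policy {duplicate_policy!r}")
        n_before = len(df)
        df = df[~df.index.duplicated(keep="first")]
        report.note(f"kept first occurrence of duplicated gene rows",
                    dropped=n_before - len(df))
        genes = [str(g) for g in df.index]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-integer value {df.iat[i, j]!r} at gene "
            f"{genes[i]!r}, sample {samples[j]!r}"
        )
    values = numeric.to_numpy()
    if not np.array_equal(values, np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise FormatError(
            f"{path}: non-integer value {df.iat[i, j]!r} at gene "
            f"{genes[i]!r}, sample {samples[j]!r}"
        )
    return GisticTable(genes, list(samples), values.astype(np.int8), report)


def write_gistic_matrix(table: GisticTable, path: str | Path) -> None:
    df = pd.DataFrame(table.scores, index=table.gene_ids, columns=table.patient_ids)
    df.index.name = "Hugo_Symbol"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene loci
# ---------------------------------------------------------------------------

@dataclass
class GeneLocusTable:
    """Per-gene chromosome label and transcription start site (1-based bp)."""

    table: pd.DataFrame  # index: symbol; columns: chromosome, tss_bp

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate gene symbol in locus table: {dup!r}")
        if (self.table["tss_bp"] < 0).any():
            sym = self.table.index[self.table["tss_bp"] < 0][0]
            raise FormatError(f"negative transcription start site for {sym!r}")

    @property
    def symbols(self) -> list[str]:
        return list(self.table.index)

    def chromosome(self, symbol: str) -> str:
        return str(self.table.at[symbol, "chromosome"])

    def tss(self, symbol: str) -> int:
        return int(self.table.at[symbol, "tss_bp"])

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.table.index


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def read_gene_loci(path: str | Path,
                   valid_chromosomes: Iterable[str] | None = None) -> GeneLocusTable:
    """Read gene loci from a 3-column TSV (symbol, chromosome, tss_bp) or BED.

    BED rows (chrom, start, end, name[, score, strand]) use 0-based half-open
    coordinates; they are converted to the internal 1-based TSS convention as
    start+1 on the plus strand and end on the minus strand (plus assumed when
    no strand column is present).
    """
    path = Path(path)
    rows: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("symbol\t"):
                continue
            fields = line.split("\t")
            if len(fields) >= 4 and _is_int(fields[1]) and _is_int(fields[2]):
                # BED: chrom start end name [score strand]
                chrom, start, end, symbol = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) >= 6 else "+"
                tss = end if strand == "-" else start + 1
            elif len(fields) == 3:
                symbol, chrom = fields[0], fields[1]
                if not _is_int(fields[2]):
                    raise FormatError(f"{path}:{lineno}: tss_bp {fields[2]!r} is not an integer")
                tss = int(fields[2])
            else:
                raise FormatError(f"{path}:{lineno}: expected 3-column TSV or BED row")
            if tss < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate for {symbol!r}")
            if valid_chromosomes is not None and chrom not in set(valid_chromosomes):
                raise FormatError(f"{path}:{lineno}: chromosome {chrom!r} not in declared set")
            rows.append((symbol, chrom, tss))
    df = pd.DataFrame(rows, columns=["symbol", "chromosome", "tss_bp"]).set_index("symbol")
    return GeneLocusTable(df)


def write_gene_loci(loci: GeneLocusTable, path: str | Path) -> None:
    df = loci.table.reset_index()
    df.to_csv(path, sep="\t", index=False, header=["symbol", "chromosome", "tss_bp"])


# ---------------------------------------------------------------------------
# Pathway annotations (GMT)
# ---------------------------------------------------------------------------

@dataclass
class PathwayAnnotation:
    """Pathway -> member-gene sets plus the derived gene -> pathway view."""

    pathways: dict[str, frozenset[str]]
    report: LoadReport = field(default_factory=LoadReport, compare=False)

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise FormatError(f"empty pathway {pid!r}")
        view: dict[str, set[str]] = {}
        for pid, genes in self.pathways.items():
            for g in genes:
                view.setdefault(g, set()).add(pid)
        self.gene_pathways: dict[str, frozenset[str]] = {
            g: frozenset(p) for g, p in view.items()
        }

    @property
    def universe_size(self) -> int:
        return len(self.pathways)

    def restrict_to_universe(self, genes: Iterable[str]) -> "PathwayAnnotation":
        """Drop genes outside ``genes`` and any pathway left empty.

        The pathway universe shrinks accordingly, so over-representation
        tests are not diluted by pathways no analysed gene can hit.
        """
        keep = set(genes)
        restricted = {}
        dropped = 0
        for pid, members in self.pathways.items():
            inter = members & keep
            if inter:
                restricted[pid] = frozenset(inter)
            else:
                dropped += 1
        if not restricted:
            raise FormatError("no pathways left after restricting to the gene universe")
        report = LoadReport()
        if dropped:
            report.note(f"dropped {dropped} pathways empty after restriction",
                        dropped=dropped)
        return PathwayAnnotation(restricted, report)


def read_gmt(path: str | Path) -> PathwayAnnotation:
    """Read standard GMT: name, description, then member genes, tab-separated."""
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    report = LoadReport()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not any(fields[2:]):
                report.note(f"line {lineno}: fewer than 3 fields, skipped", skipped=1)
                warnings.warn(f"{path}:{lineno}: GMT line with <3 fields skipped")
                continue
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway {name!r}")
            pathways[name] = genes
    if not pathways:
        raise FormatError(f"{path}: no pathways")
    return PathwayAnnotation(pathways, report)


def write_gmt(ann: PathwayAnnotation, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        for pid in sorted(ann.pathways):
            desc = (descriptions or {}).get(pid, "na")
            genes = "\t".join(sorted(ann.pathways[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# GARP essentiality screens
# ---------------------------------------------------------------------------

@dataclass
class GarpTable:
    """Gene x cell-line GARP scores with a companion mutation-status table.

    GARP scores are real-valued (typically in [-10, +5]); lower means more
    essential.  Missing scores are NaN and are excluded pairwise from median
    computations downstream, never imputed.  ``status`` is cell-line x gene
    with codes in {WT, HOMDEL, SOMATIC_MUT}; the two tables share the same
    cell-line identifiers.
    """

    scores: pd.DataFrame  # genes x cell lines, float, NaN = missing
    status: pd.DataFrame  # cell lines x genes, str codes
    report: LoadReport = field(default_factory=LoadReport, compare=False)

    def __post_init__(self) -> None:
        if list(self.scores.columns) != list(self.status.index):
            raise FormatError("GARP score and status tables disagree on cell lines")
        bad = ~self.status.isin(STATUS_CODES)
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"unknown mutation status {self.status.iat[i, j]!r} for cell line "
                f"{self.status.index[i]!r}, gene {self.status.columns[j]!r}"
            )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)


def read_garp(score_path: str | Path, status_path: str | Path) -> GarpTable:
    """Read GARP scores and mutation status, aligning on shared cell lines."""
    scores = pd.read_csv(score_path, sep="\t", index_col=0,
                         na_values=["NA", "NaN", ""], keep_default_na=False)
    scores = scores.astype(float)
    status = pd.read_csv(status_path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    shared = [c for c in scores.columns if c in set(status.index)]
    if not shared:
        raise FormatError("no cell lines shared between GARP scores and status tables")
    report = LoadReport()
    dropped = (len(scores.columns) - len(shared)) + (len(status.index) - len(shared))
    if dropped:
        report.note(f"dropped {dropped} cell lines absent from one table", dropped=dropped)
    return GarpTable(scores[shared], status.loc[shared], report)


def write_garp(garp: GarpTable, score_path: str | Path, status_path: str | Path) -> None:
    scores = garp.scores.copy()
    scores.index.name = "gene"
    scores.to_csv(score_path, sep="\t", na_rep="NA")
    status = garp.status.copy()
    status.index.name = "cell_line"
    status.to_csv(status_path, sep="\t")


# ---------------------------------------------------------------------------
# Generic binary matrices (consensus-gene handoff between CLI stages)
# ---------------------------------------------------------------------------

def read_binary_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, [0, 1]).all():
        raise FormatError(f"{path}: matrix is not binary")
    return list(map(str, df.index)), list(map(str, df.columns)), values.astype(np.uint8)


def write_binary_matrix(row_ids: Sequence[str], col_ids: Sequence[str],
                        values: np.ndarray, path: str | Path,
                        index_name: str = "id") -> None:
    df = pd.DataFrame(np.asarray(values, dtype=int), index=list(row_ids),
                      columns=list(col_ids))
    df.index.name = index_name
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["cluster_a", "cluster_b", "M_a", "M_b", "M_ab", "HDMI", "p_value"]
CLUSTER_COLUMNS = ["cluster_id", "exemplar", "chromosome", "members"]
SL_COLUMNS = [
    "gene_x", "gene_y", "cluster_a", "cluster_b", "evidence",
    "garp_variant", "med_x_wt", "med_x_partner_alt", "med_y_wt", "med_y_partner_alt",
    "n_both_wt", "n_y_alt", "n_x_alt",
    "k_shared", "K_x", "K_y", "N_pathways", "p_pathway_raw", "p_pathway_adj",
    "collateral_partners",
]


def write_results(me_results, sl_calls, out_dir: str | Path, clusters=None) -> None:
    """Write the three fixed-schema result TSVs into ``out_dir``.

    ``pairs.tsv`` rows are ordered by (p ascending, HDMI descending,
    lexicographic cluster pair) so repeated runs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "cluster_a": r.cluster_a, "cluster_b": r.cluster_b,
            "M_a": r.m_a, "M_b": r.m_b, "M_ab": r.m_ab,
            "HDMI": f"{r.hdmi:.6g}", "p_value": f"{r.p_value:.6g}",
        }
        for r in sorted(
            me_results,
            key=lambda r: (r.p_value, -r.hdmi, r.cluster_a, r.cluster_b),
        )
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(out / "pairs.tsv", sep="\t", index=False)

    sl_rows = [c.as_row() for c in sl_calls]
    pd.DataFrame(sl_rows, columns=SL_COLUMNS).to_csv(out / "sl_calls.tsv", sep="\t", index=False)

    cl_rows = []
    if clusters:
        for cid in sorted(clusters):
            c = clusters[cid]
            cl_rows.append({
                "cluster_id": cid, "exemplar": c.exemplar,
                "chromosome": c.chromosome, "members": ",".join(c.members),
            })
    pd.DataFrame(cl_rows, columns=CLUSTER_COLUMNS).to_csv(out / "clusters.tsv", sep="\t", index=False)
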