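"""Cytosine-level methylation calls, context annotation, and the analysis matrix.

The mitochondrial genome is circular and double-stranded; methylation calls are
strand-specific. Files use Bismark cytosine-report strand symbols ('+'/'-'),
which map to the heavy (H) and light (L) chain respectively; the mapping is
configurable for other conventions. Positions are 1-based on the canonical,
unpadded circular reference.

Input counts are assumed to be base-quality-filtered upstream (read trimming at
Q30 happens before alignment); this module only applies coverage and presence
filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CytosineSite",
    "MethylationMatrix",
    "CONTEXTS",
    "COMPLEMENT",
    "methylation_level",
    "classify_context",
    "annotate_contexts",
    "cytosine_positions",
    "read_cytosine_report",
    "write_cytosine_report",
    "filter_by_coverage",
    "build_matrix",
    "overlap_sites",
]

CONTEXTS = ("CpG", "CHG", "CHH")

#: file strand symbol -> chain label
DEFAULT_STRAND_MAP = {"+": "H", "-": "L"}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

REPORT_COLUMNS = [
    "position",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


@dataclass(frozen=True, order=True)
class CytosineSite:
    """A strand-specific cytosine position on the circular reference.

    Parameters
    ----------
    position : int
        1-based coordinate on the unpadded circular mitochondrial reference.
    strand : str
        ``"H"`` (heavy chain, '+' in report files) or ``"L"`` (light chain).
    context : str, optional
        Sequence context ``CpG``, ``CHG`` or ``CHH`` (H = A, C or T).
    gene : str, optional
        Gene label, if annotated.
    """

    position: int
    strand: str
    context: str | None = None
    gene: str | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.context is not None and self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.strand)


def methylation_level(num_c: int | np.ndarray, num_t: int | np.ndarray) -> float | np.ndarray:
    """Percent methylation, ``100 * num_c / (num_c + num_t)``.

    ``num_c`` is the count of methylated (unconverted) cytosine reads, ``num_t``
    the count of unmethylated (bisulfite-converted) reads. Zero total coverage
    is an error: the coverage filter must run first, so zero-coverage cells
    cannot legitimately reach this function.
    """
    num_c = np.asarray(num_c)
    num_t = np.asarray(num_t)
    if np.any(num_c < 0) or np.any(num_t < 0):
        raise ValueError("counts must be nonnegative")
    total = num_c + num_t
    if np.any(total == 0):
        raise ValueError("zero coverage: filter calls by coverage before computing levels")
    out = 100.0 * num_c / total
    return float(out) if out.ndim == 0 else out


def classify_context(reference: str, position: int, strand: str) -> str:
    """Classify the sequence context of a cytosine on a circular reference.

    The two bases immediately downstream of the cytosine *on its own strand*
    are inspected, wrapping around the origin (the genome is circular). Next
    base G gives CpG; otherwise a G two bases downstream gives CHG; otherwise
    CHH. On the light chain (file strand '-'), downstream means decreasing
    plus-strand coordinates and bases are complemented.
    """
    n = len(reference)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside reference of length {n}")
    i = position - 1
    if strand in ("H", "+"):
        if reference[i] != "C":
            raise ValueError(f"base at position {position} on H strand is {reference[i]!r}, not C")
        nxt = reference[(i + 1) % n]
        nxt2 = reference[(i + 2) % n]
    elif strand in ("L", "-"):
        if reference[i] != "G":
            raise ValueError(
                f"base at position {position} is {reference[i]!r}; L-strand cytosines "
                "sit opposite a plus-strand G"
            )
        nxt = COMPLEMENT[reference[(i - 1) % n]]
        nxt2 = COMPLEMENT[reference[(i - 2) % n]]
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if nxt == "G":
        return "CpG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def trinucleotide(reference: str, position: int, strand: str) -> str:
    """The cytosine and its two downstream bases on the cytosine's own strand."""
    n = len(reference)
    i = position - 1
    if strand in ("H", "+"):
        return reference[i] + reference[(i + 1) % n] + reference[(i + 2) % n]
    return "".join(COMPLEMENT[reference[(i - k) % n]] for k in range(3))


def cytosine_positions(reference: str) -> list[tuple[int, str]]:
    """All (position, strand) pairs carrying a cytosine, both chains.

    H-chain cytosines are plus-strand ``C``s; L-chain cytosines sit opposite
    plus-strand ``G``s. Sorted by position then strand (H before L).
    """
    sites = []
    for i, base in enumerate(reference):
        if base == "C":
            sites.append((i + 1, "H"))
        elif base == "G":
            sites.append((i + 1, "L"))
    return sites


def annotate_contexts(reference: str, sites: Iterable[tuple[int, str]]) -> pd.DataFrame:
    """Context and trinucleotide annotation for (position, strand) pairs."""
    rows = [
        {
            "position": pos,
            "strand": strand,
            "context": classify_context(reference, pos, strand),
            "trinucleotide": trinucleotide(reference, pos, strand),
        }
        for pos, strand in sites
    ]
    df = pd.DataFrame(rows, columns=["position", "strand", "context", "trinucleotide"])
    return df.set_index(["position", "strand"])


# ---------------------------------------------------------------------------
# cytosine report IO
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path: str | Path,
    genome_length: int | None = None,
    strand_map: Mapping[str, str] = DEFAULT_STRAND_MAP,
) -> pd.DataFrame:
    """Read a tab-delimited cytosine report into a calls table.

    One row per cytosine: position, strand, count_methylated,
    count_unmethylated, context, trinucleotide (Bismark cytosine-report column
    order, without the chromosome column — the reference is a single molecule).
    Strand symbols are mapped to chain labels H/L. Malformed rows raise with
    their 1-based line number.

    Returns a DataFrame with columns ``position, strand, count_methylated,
    count_unmethylated, context, trinucleotide`` and a computed ``coverage``
    column.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(REPORT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(REPORT_COLUMNS)} tab-separated "
                    f"fields, got {len(fields)}"
                )
            pos_s, strand_s, mc_s, uc_s, ctx, tri = fields
            try:
                pos, mc, uc = int(pos_s), int(mc_s), int(uc_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if mc < 0 or uc < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if pos < 1 or (genome_length is not None and pos > genome_length):
                raise ValueError(f"{path}:{lineno}: position {pos} out of range")
            if strand_s not in strand_map:
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand_s!r}")
            if ctx not in CONTEXTS:
                raise ValueError(f"{path}:{lineno}: unknown context {ctx!r}")
            rows.append((pos, strand_map[strand_s], mc, uc, ctx, tri))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df["coverage"] = df["count_methylated"] + df["count_unmethylated"]
    return df


def write_cytosine_report(
    calls: pd.DataFrame,
    path: str | Path,
    overwrite: bool = False,
    strand_map: Mapping[str, str] = DEFAULT_STRAND_MAP,
) -> Path:
    """Write a calls table to the tab-delimited cytosine-report dialect.

    Refuses to overwrite an existing file unless ``overwrite=True``. The
    write-then-read round trip is exact (integer counts, positions, strands).
    """
    path = Path(path)
    if len(calls) == 0:
        raise ValueError("refusing to write an empty call set")
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    inverse = {chain: sym for sym, chain in strand_map.items()}
    out = calls[REPORT_COLUMNS].copy()
    out["strand"] = out["strand"].map(inverse)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)
    return path


def filter_by_coverage(calls: pd.DataFrame, min_coverage: int = 30) -> pd.DataFrame:
    """Retain calls whose total read count is at least ``min_coverage``.

    Mirrors methylKit's ``filterByCoverage(lo.count=30)``: a site must have
    ``count_methylated + count_unmethylated >= min_coverage`` to keep its call.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    cov = calls["count_methylated"] + calls["count_unmethylated"]
    return calls.loc[cov >= min_coverage].reset_index(drop=True)


# ---------------------------------------------------------------------------
# the analysis matrix
# ---------------------------------------------------------------------------

class MethylationMatrix:
    """Samples x cytosine-sites grid of methylation percentages.

    Every retained site passed the coverage filter in *every* sample (the
    "detectable in all samples" presence rule), so the grid has no missing
    cells. Columns are a (position, strand) MultiIndex sorted by position then
    strand; ``sites`` carries context annotation per column.

    Attributes
    ----------
    levels : pd.DataFrame
        Percent methylation, samples x sites.
    coverage : pd.DataFrame
        Total read counts, same shape.
    sites : pd.DataFrame
        Indexed by (position, strand); columns ``context`` and
        ``trinucleotide``.
    area : str or None
        Brain-area label (``NAcc``/``PFC``) if the matrix is area-specific.
    """

    def __init__(
        self,
        levels: pd.DataFrame,
        coverage: pd.DataFrame,
        sites: pd.DataFrame,
        area: str | None = None,
    ):
        if not levels.columns.equals(coverage.columns) or not levels.index.equals(coverage.index):
            raise ValueError("levels and coverage grids must be aligned")
        if not levels.columns.equals(sites.index):
            raise ValueError("site annotation must match matrix columns")
        self.levels = levels
        self.coverage = coverage
        self.sites = sites
        self.area = area

    @property
    def sample_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def site_keys(self) -> list[tuple[int, str]]:
        return list(self.levels.columns)

    @property
    def n_sites(self) -> int:
        return self.levels.shape[1]

    def subset_context(self, subset: str) -> "MethylationMatrix":
        """Restrict to ``all``, ``CpG_only`` or ``nonCpG_only`` site subsets."""
        if subset == "all":
            return self
        if subset == "CpG_only":
            mask = self.sites["context"] == "CpG"
        elif subset == "nonCpG_only":
            mask = self.sites["context"] != "CpG"
        else:
            raise ValueError(f"unknown context subset {subset!r}")
        keep = self.sites.index[mask]
        return MethylationMatrix(
            self.levels[keep], self.coverage[keep], self.sites.loc[keep], area=self.area
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(
            self.levels.loc[list(sample_ids)],
            self.coverage.loc[list(sample_ids)],
            self.sites,
            area=self.area,
        )

    def to_tsv(self, levels_path: str | Path, sites_path: str | Path) -> None:
        """Serialize the grid (sites x samples) and site annotation as TSV."""
        grid = self.levels.T.copy()
        grid.index.names = ["position", "strand"]
        grid.to_csv(levels_path, sep="\t")
        ann = self.sites.copy()
        ann.index.names = ["position", "strand"]
        ann.to_csv(sites_path, sep="\t")

    def __repr__(self) -> str:
        area = f" area={self.area}" if self.area else ""
        return f"<MethylationMatrix {len(self.levels)} samples x {self.n_sites} sites{area}>"


def build_matrix(
    call_sets: Mapping[str, pd.DataFrame],
    min_coverage: int = 30,
    area: str | None = None,
) -> MethylationMatrix:
    """Assemble the analysis matrix from per-sample call tables.

    A site (position, strand) is retained iff its coverage is at least
    ``min_coverage`` in *every* sample — the detectable-in-all-samples rule that
    leaves a fully populated grid. Duplicate (position, strand) rows within
    one sample are an error.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least 2 samples to build a matrix")
    cov_cols = {}
    lev_cols = {}
    annotation = None
    for sample_id, calls in call_sets.items():
        keyed = calls.set_index(["position", "strand"])
        if keyed.index.has_duplicates:
            dup = keyed.index[keyed.index.duplicated()][0]
            raise ValueError(f"duplicate site {dup} in sample {sample_id!r}")
        cov = keyed["count_methylated"] + keyed["count_unmethylated"]
        cov_cols[sample_id] = cov
        lev_cols[sample_id] = 100.0 * keyed["count_methylated"] / cov.where(cov > 0)
        ann = keyed[["context", "trinucleotide"]] if "trinucleotide" in keyed else keyed[["context"]]
        annotation = ann if annotation is None else annotation.combine_first(ann)
    coverage = pd.DataFrame(cov_cols).T.fillna(0).astype(int)
    levels = pd.DataFrame(lev_cols).T
    keep = coverage.columns[(coverage >= min_coverage).all(axis=0)]
    keep = sorted(keep)  # position, then strand (H < L)
    coverage = coverage[keep]
    levels = levels[keep]
    sites = annotation.loc[keep]
    levels.columns = pd.MultiIndex.from_tuples(keep, names=["position", "strand"])
    coverage.columns = levels.columns
    sites.index = levels.columns
    return MethylationMatrix(levels, coverage, sites, area=area)


def overlap_sites(
    matrix_a: MethylationMatrix, matrix_b: MethylationMatrix
) -> list[tuple[int, str]]:
    """Sites shared by two matrices, keyed by (position, strand), order-stable."""
    in_b = set(matrix_b.site_keys)
    return [k for k in matrix_a.site_keys if k in in_b]
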