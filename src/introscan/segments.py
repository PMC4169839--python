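"""Donor-segment construction and zygosity design matrices.

An introgression population is a set of inbred lines that each carry a small
number of chromosome segments from an exotic donor in the otherwise uniform
genetic background of an elite recipient.  Markers whose donor-allele dosage
patterns are identical across the whole population are in complete linkage
disequilibrium and carry no independent information; maximal runs of
consecutive such markers on one chromosome are collapsed into *donor
segments*.  Each segment contributes one column to the design matrix ``Z``
whose entries 0/1/2 count the donor alleles (segment zygosity) carried by a
line.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

MARKER_COLUMNS = ("marker_id", "chromosome", "position_cM")

__all__ = [
    "GenotypeValidationError",
    "MarkerGenotypes",
    "DonorSegment",
    "SegmentMap",
    "DesignMatrix",
    "RankStatus",
    "build_segments",
    "build_design_matrix",
    "rank_status",
    "render_graphical_genotypes",
]


class GenotypeValidationError(ValueError):
    """A genotype table violates the dosage or genetic-map invariants."""


def _as_marker_frame(markers) -> pd.DataFrame:
    if isinstance(markers, pd.DataFrame):
        missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
        if missing:
            raise GenotypeValidationError(
                f"marker table lacks required column(s) {missing}"
            )
        frame = markers.loc[:, list(MARKER_COLUMNS)].reset_index(drop=True)
    else:
        frame = pd.DataFrame(list(markers), columns=list(MARKER_COLUMNS))
    frame["marker_id"] = frame["marker_id"].astype(str)
    frame["chromosome"] = frame["chromosome"].astype(str)
    frame["position_cM"] = frame["position_cM"].astype(float)
    return frame


@dataclasses.dataclass
class MarkerGenotypes:
    """Lines x markers donor-allele dosage matrix with a genetic map.

    Parameters
    ----------
    line_ids
        Identifiers of the N lines (rows of ``dosage``); must be unique.
    markers
        Marker map: a DataFrame with columns ``marker_id``, ``chromosome``,
        ``position_cM``, or an iterable of (marker_id, chromosome,
        position_cM) tuples.  Positions are cM from the chromosome start and
        must be non-decreasing within each chromosome.
    dosage
        N x M integer matrix of donor-allele counts in {0, 1, 2}.  Missing
        values are rejected; imputation is out of scope.
    """

    line_ids: list
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(l) for l in self.line_ids]
        self.markers = _as_marker_frame(self.markers)
        dosage = np.asarray(self.dosage)
        if dosage.ndim != 2:
            raise GenotypeValidationError("dosage must be a 2-D matrix")
        n, m = dosage.shape
        if n < 2 or m < 1:
            raise GenotypeValidationError(
                f"need at least 2 lines and 1 marker, got {n} x {m}"
            )
        if len(self.line_ids) != n:
            raise GenotypeValidationError(
                f"{len(self.line_ids)} line ids for {n} dosage rows"
            )
        if len(set(self.line_ids)) != n:
            dupes = {l for l in self.line_ids if self.line_ids.count(l) > 1}
            raise GenotypeValidationError(f"duplicated line id(s): {sorted(dupes)}")
        if len(self.markers) != m:
            raise GenotypeValidationError(
                f"{len(self.markers)} map entries for {m} dosage columns"
            )
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            raise GenotypeValidationError(
                f"duplicated marker id(s): {sorted(ids[ids.duplicated()].unique())}"
            )
        if not np.all(np.isfinite(dosage.astype(float))):
            r, c = np.argwhere(~np.isfinite(dosage.astype(float)))[0]
            raise GenotypeValidationError(
                f"non-finite dosage for line {self.line_ids[r]!r}, "
                f"marker {ids.iloc[c]!r}"
            )
        bad = ~np.isin(dosage, (0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise GenotypeValidationError(
                f"dosage {dosage[r, c]!r} outside {{0,1,2}} for line "
                f"{self.line_ids[r]!r}, marker {ids.iloc[c]!r}"
            )
        pos = self.markers["position_cM"].to_numpy()
        if (pos < 0).any():
            raise GenotypeValidationError("negative cM position in marker map")
        for chrom, idx in self._chromosome_blocks():
            p = pos[idx]
            if np.any(np.diff(p) < 0):
                raise GenotypeValidationError(
                    f"positions not non-decreasing on chromosome {chrom!r}"
                )
        self.dosage = dosage.astype(np.int8)

    # -- convenience ------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def chromosomes(self) -> list:
        """Chromosome ids in order of first appearance."""
        return list(dict.fromkeys(self.markers["chromosome"]))

    def _chromosome_blocks(self):
        """Yield (chromosome, marker index array), preserving file order."""
        chrom = self.markers["chromosome"].to_numpy()
        for c in dict.fromkeys(chrom):
            yield c, np.flatnonzero(chrom == c)

    def marker_positions(self, chromosome) -> np.ndarray:
        sel = self.markers["chromosome"] == str(chromosome)
        return self.markers.loc[sel, "position_cM"].to_numpy()

    def dosage_at(self, chromosome, position_cM: float) -> np.ndarray:
        """Donor dosage of every line at the marker nearest to a position.

        Ties between two equidistant flanking markers resolve to the left
        (lower-position) marker.
        """
        chrom = self.markers["chromosome"].to_numpy()
        idx = np.flatnonzero(chrom == str(chromosome))
        if idx.size == 0:
            raise KeyError(f"no markers on chromosome {chromosome!r}")
        pos = self.markers["position_cM"].to_numpy()[idx]
        j = idx[int(np.argmin(np.abs(pos - position_cM)))]
        return self.dosage[:, j]


@dataclasses.dataclass
class DonorSegment:
    """A maximal run of markers with identical donor-dosage columns."""

    segment_id: str
    chromosome: str
    start_cM: float
    end_cM: float
    marker_ids: list
    dosage_column: np.ndarray  # length-N vector in {0,1,2}, not all zero

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def carrier_count(self) -> int:
        """Number of lines with nonzero donor dosage at this segment."""
        return int(np.count_nonzero(self.dosage_column))

    def contains(self, chromosome, position_cM: float) -> bool:
        """Closed-interval span containment on the segment's chromosome."""
        return (
            str(chromosome) == self.chromosome
            and self.start_cM <= position_cM <= self.end_cM
        )


@dataclasses.dataclass
class SegmentMap:
    """Ordered donor segments (chromosome, then start position) of a population."""

    segments: list
    line_ids: list
    source: MarkerGenotypes | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_ids(self) -> list:
        return [s.segment_id for s in self.segments]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            row = {
                "segment_id": s.segment_id,
                "chromosome": s.chromosome,
                "start_cM": s.start_cM,
                "end_cM": s.end_cM,
                "n_markers": s.n_markers,
            }
            row.update(
                {line: int(d) for line, d in zip(self.line_ids, s.dosage_column)}
            )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclasses.dataclass
class DesignMatrix:
    """N x S zygosity-coded design matrix Z (rows lines/plots, columns segments).

    Row ids may repeat when the matrix has been expanded to plot-level
    observations; column ids are segment ids and must be unique.
    """

    Z: np.ndarray
    row_ids: list
    col_ids: list

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        if Z.ndim != 2:
            raise GenotypeValidationError("Z must be 2-D")
        if Z.shape != (len(self.row_ids), len(self.col_ids)):
            raise GenotypeValidationError(
                f"Z shape {Z.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        if not np.isin(Z, (0.0, 1.0, 2.0)).all():
            raise GenotypeValidationError("Z entries must be in {0,1,2}")
        zero = ~Z.any(axis=0)
        if zero.any():
            raise GenotypeValidationError(
                f"all-zero design column(s): "
                f"{[self.col_ids[j] for j in np.flatnonzero(zero)]}"
            )
        if len(set(self.col_ids)) != len(self.col_ids):
            raise GenotypeValidationError("duplicated design column ids")
        self.Z = Z

    @property
    def n_rows(self) -> int:
        return self.Z.shape[0]

    @property
    def n_segments(self) -> int:
        return self.Z.shape[1]

    def expand(self, row_ids: Sequence) -> "DesignMatrix":
        """Replicate rows to observation (plot) level.

        ``row_ids`` is the per-observation line id sequence; each id must be
        a row of this matrix.  Used to analyse replicated plot values with
        the line-level genotypes.
        """
        index = {l: i for i, l in enumerate(self.row_ids)}
        try:
            rows = [index[str(l)] for l in row_ids]
        except KeyError as err:
            raise KeyError(f"line id {err.args[0]!r} not present in design") from None
        return DesignMatrix(self.Z[rows], [str(l) for l in row_ids], list(self.col_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z.astype(int), index=self.row_ids, columns=self.col_ids)


class RankStatus(NamedTuple):
    status: str  # "full_column_rank" | "rank_deficient"
    rank: int
    n_columns: int


def build_segments(geno: MarkerGenotypes, allow_empty: bool = False) -> SegmentMap:
    """Collapse markers in complete LD into donor segments.

    Within each chromosome, maximal runs of consecutive markers with
    *identical* dosage columns form one segment (complete linkage
    disequilibrium in the population is implemented as exact column
    equality).  Markers with an all-zero column (recipient allele in every
    line) belong to no segment; an interior all-zero marker breaks a run.
    The segment span is the closed interval between the first and last
    member marker position.

    Parameters
    ----------
    geno
        Validated marker genotypes.
    allow_empty
        If the dosage matrix contains no donor allele at all, return an
        empty SegmentMap instead of raising.
    """
    ids = geno.markers["marker_id"].to_numpy()
    pos = geno.markers["position_cM"].to_numpy()
    segments: list[DonorSegment] = []
    used = set()
    for chrom, idx in geno._chromosome_blocks():
        run_start = 0
        cols = geno.dosage[:, idx]
        k = len(idx)
        for j in range(1, k + 1):
            if j < k and np.array_equal(cols[:, j], cols[:, run_start]):
                continue
            column = cols[:, run_start]
            if column.any():
                members = idx[run_start:j]
                seg_id = f"{chrom}:{pos[members[0]]:g}-{pos[members[-1]]:g}"
                while seg_id in used:  # duplicate positions on a chromosome
                    seg_id += "'"
                used.add(seg_id)
                segments.append(
                    DonorSegment(
                        segment_id=seg_id,
                        chromosome=str(chrom),
                        start_cM=float(pos[members[0]]),
                        end_cM=float(pos[members[-1]]),
                        marker_ids=[str(m) for m in ids[members]],
                        dosage_column=column.copy(),
                    )
                )
            run_start = j
    if not segments and not allow_empty:
        raise GenotypeValidationError(
            "no donor segment found (dosage matrix is all zero); "
            "pass allow_empty=True to accept an empty segment map"
        )
    return SegmentMap(segments=segments, line_ids=list(geno.line_ids), source=geno)


def build_design_matrix(smap: SegmentMap) -> DesignMatrix:
    """Assemble the N x S zygosity design matrix Z from a segment map."""
    if smap.n_segments == 0:
        raise GenotypeValidationError("cannot build a design matrix without segments")
    Z = np.column_stack([s.dosage_column for s in smap.segments])
    return DesignMatrix(Z=Z, row_ids=list(smap.line_ids), col_ids=smap.segment_ids)


def rank_status(design: DesignMatrix | np.ndarray) -> RankStatus:
    """Numerical column-rank classification of Z.

    Singular values below ``max(N, S) * eps * sigma_max`` count as zero
    (numpy's default rank tolerance).  Rank-deficient designs arise whenever
    donor segments overlap between lines or S > N; they are not estimable by
    ordinary least squares but remain usable with ridge shrinkage.
    """
    Z = design.Z if isinstance(design, DesignMatrix) else np.asarray(design, float)
    rank = int(np.linalg.matrix_rank(Z))
    s = Z.shape[1]
    status = "full_column_rank" if rank == s else "rank_deficient"
    return RankStatus(status=status, rank=rank, n_columns=s)


def render_graphical_genotypes(geno: MarkerGenotypes) -> str:
    """Plain-text graphical genotypes: one row per line, one char per marker.

    ``.`` recipient homozygote, ``h`` heterozygote (dosage 1), ``D`` donor
    homozygote (dosage 2); chromosomes separated by ``|``.
    """
    glyph = {0: ".", 1: "h", 2: "D"}
    blocks = list(geno._chromosome_blocks())
    width = max(len(l) for l in geno.line_ids)
    header = " " * width + "  " + " ".join(
        str(c).ljust(len(idx)) for c, idx in blocks
    )
    lines = [header.rstrip()]
    for i, line in enumerate(geno.line_ids):
        parts = [
            "".join(glyph[int(d)] for d in geno.dosage[i, idx]) for _, idx in blocks
        ]
        lines.append(f"{line.ljust(width)}  " + "|".join(parts))
    return "\n".join(lines) + "\n"
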