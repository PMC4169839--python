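"""Synthetic introgression populations and the power / false-positive study.

Two hypothetical populations on a genome of three 120-cM chromosomes:

* the *ideal* population — 9 doubled-haploid-like lines, each homozygous for
  one 40-cM donor block, blocks tiling the genome without overlap, so the
  collapsed design matrix is ``2 * I_9``;
* the *overlapping* population — random homozygous donor blocks of varying
  length per line, accepted only when the collapsed segments outnumber the
  lines (S > N), at least one pair of lines shares donor material, and at
  least 95% of the markers are covered by some line.

Quantitative traits are additive and oligogenic: 2, 4 or 6 causal loci at
random genome positions, each favourable donor allele worth
``donor_advantage / (2 * n_loci)`` units so a full donor genotype outyields
the recipient by ``donor_advantage`` (default 100).  Environmental noise is
scaled to a target line-mean heritability h^2.

The power experiment repeats trait simulation, model fitting and segment
testing over many runs and records, per run, the number of correctly
detected causal loci (a locus counts as detected when a significant
segment's span contains it) and the number of significant segments that
contain no causal locus (false positives).

Analyses are carried out on replicated plot values (default 4 plots per
line) with replicated recipient checks included, which provides the
residual degrees of freedom required by the LSQ F-tests and a fine-grained
permutation null; line-mean analysis (``n_reps=1``) remains available.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .estimators import PhenotypeVector, fit_blup, fit_lsq, fit_rmlv
from .segments import (
    DesignMatrix,
    MarkerGenotypes,
    SegmentMap,
    build_design_matrix,
    build_segments,
)
from .significance import (
    PermutationConfig,
    SegmentTestResult,
    permutation_test,
    test_lsq,
)

__all__ = [
    "GenomeSpec",
    "TraitArchitecture",
    "PowerResult",
    "RECIPIENT_ID",
    "POPULATION2_SEED",
    "make_ideal_population",
    "make_overlapping_population",
    "simulate_trait",
    "classify_detections",
    "run_power_experiment",
    "worked_example",
]

logger = logging.getLogger(__name__)

RECIPIENT_ID = "REC"
#: default seed of the canonical overlapping-population fixture
POPULATION2_SEED = 2014


@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """Genome layout used by the synthetic populations."""

    n_chromosomes: int = 3
    chromosome_length_cM: float = 120.0
    marker_spacing_cM: float = 10.0

    def __post_init__(self) -> None:
        if (
            self.n_chromosomes <= 0
            or self.chromosome_length_cM <= 0
            or self.marker_spacing_cM <= 0
        ):
            raise ValueError("all GenomeSpec fields must be positive")

    @property
    def total_length_cM(self) -> float:
        return self.n_chromosomes * self.chromosome_length_cM

    @property
    def chromosome_ids(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def marker_positions(self) -> np.ndarray:
        """Per-chromosome marker positions at the midpoints of spacing bins.

        Midpoint registration keeps block boundaries (multiples of the
        spacing) off the marker grid, so non-overlapping donor blocks never
        share a boundary marker.
        """
        s = self.marker_spacing_cM
        return np.arange(s / 2.0, self.chromosome_length_cM, s)

    def marker_table(self) -> list:
        rows = []
        for c in self.chromosome_ids:
            for p in self.marker_positions():
                rows.append((f"m_{c}_{p:g}", c, float(p)))
        return rows


@dataclasses.dataclass
class TraitArchitecture:
    """Causal loci (chromosome, position cM, allele effect) and heritability."""

    loci: list  # of (chromosome, position_cM, effect)
    heritability: float
    donor_advantage: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.heritability < 1:
            raise ValueError(
                f"heritability must be in (0, 1), got {self.heritability}"
            )
        self.loci = [(str(c), float(p), float(a)) for c, p, a in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclasses.dataclass
class PowerResult:
    """Aggregated detection counts of one method over the simulation runs."""

    method: str
    n_runs: int
    n_loci: int
    correctly_detected_sum: int
    false_positive_sum: int
    n_noncausal_total: int
    per_run: list  # of (n_correct, n_false, n_noncausal_segments)

    @property
    def correct_rate(self) -> float:
        if self.n_loci == 0:
            return 0.0
        return self.correctly_detected_sum / (self.n_runs * self.n_loci)

    @property
    def fp_rate(self) -> float:
        if self.n_noncausal_total == 0:
            return 0.0
        return self.false_positive_sum / self.n_noncausal_total


def _marker_index(spec: GenomeSpec):
    pos = spec.marker_positions()
    per_chrom = len(pos)
    return pos, per_chrom


def make_ideal_population(
    spec: GenomeSpec | None = None,
    n_lines: int = 9,
    segment_length_cM: float = 40.0,
    include_recipient: bool = False,
    allow_partial: bool = False,
) -> MarkerGenotypes:
    """Ideal introgression population: non-overlapping homozygous donor blocks.

    Line k is homozygous donor over the genome interval
    ``[k*L, (k+1)*L)`` (L = ``segment_length_cM``, chromosomes laid end to
    end), so the blocks tile the genome in line order and every marker is
    covered by exactly one line.  Requires an exact tiling
    ``n_lines * L == total genome length`` unless ``allow_partial``.
    """
    spec = spec or GenomeSpec()
    total = spec.total_length_cM
    if abs(n_lines * segment_length_cM - total) > 1e-9 and not allow_partial:
        raise ValueError(
            f"{n_lines} lines x {segment_length_cM} cM do not tile the "
            f"{total:g} cM genome; pass allow_partial=True for partial coverage"
        )
    pos, per_chrom = _marker_index(spec)
    n_markers = spec.n_chromosomes * per_chrom
    dosage = np.zeros((n_lines, n_markers), dtype=np.int8)
    for m in range(n_markers):
        global_pos = (m // per_chrom) * spec.chromosome_length_cM + pos[m % per_chrom]
        line = int(global_pos // segment_length_cM)
        if line < n_lines:
            dosage[line, m] = 2
    line_ids = [f"IL{i + 1:02d}" for i in range(n_lines)]
    if include_recipient:
        dosage = np.vstack([dosage, np.zeros((1, n_markers), dtype=np.int8)])
        line_ids = line_ids + [RECIPIENT_ID]
    return MarkerGenotypes(
        line_ids=line_ids, markers=spec.marker_table(), dosage=dosage
    )


def make_overlapping_population(
    spec: GenomeSpec | None = None,
    n_lines: int = 9,
    seg_per_line_range: tuple[int, int] = (1, 3),
    length_range_cM: tuple[float, float] = (20.0, 60.0),
    seed: int = POPULATION2_SEED,
    include_recipient: bool = False,
    min_coverage: float = 0.95,
    require_excess_segments: bool = True,
    max_tries: int = 5000,
) -> MarkerGenotypes:
    """Random overlapping-segment introgression population.

    Each line receives 1-3 homozygous donor blocks of random length
    (20-60 cM by default, snapped to the marker grid) at random genome
    positions.  Draws are repeated until the collapsed population satisfies
    all of: more segments than lines (S > N), at least one pair of lines
    sharing donor material at some marker, and marker coverage of at least
    ``min_coverage``.  Deterministic for a given seed.
    """
    spec = spec or GenomeSpec()
    lo_k, hi_k = seg_per_line_range
    lo_l, hi_l = length_range_cM
    if not (1 <= lo_k <= hi_k) or not (0 < lo_l <= hi_l):
        raise ValueError("invalid segment-count or length range")
    pos, per_chrom = _marker_index(spec)
    n_markers = spec.n_chromosomes * per_chrom
    rng = np.random.default_rng(seed)
    last_fail = ""
    for _ in range(max_tries):
        dosage = np.zeros((n_lines, n_markers), dtype=np.int8)
        for line in range(n_lines):
            for _ in range(int(rng.integers(lo_k, hi_k + 1))):
                length = rng.uniform(lo_l, hi_l)
                n_mark = max(1, round(length / spec.marker_spacing_cM))
                n_mark = min(n_mark, per_chrom)
                chrom = int(rng.integers(spec.n_chromosomes))
                start = int(rng.integers(per_chrom - n_mark + 1))
                a = chrom * per_chrom + start
                dosage[line, a : a + n_mark] = 2
        coverage = np.count_nonzero(dosage.any(axis=0)) / n_markers
        overlap = bool((np.count_nonzero(dosage > 0, axis=0) >= 2).any())
        if coverage < min_coverage:
            last_fail = f"coverage {coverage:.2f} < {min_coverage}"
            continue
        if not overlap:
            last_fail = "no overlapping donor region between lines"
            continue
        geno = MarkerGenotypes(
            line_ids=[f"IL{i + 1:02d}" for i in range(n_lines)],
            markers=spec.marker_table(),
            dosage=dosage,
        )
        smap = build_segments(geno)
        if require_excess_segments and smap.n_segments <= n_lines:
            last_fail = f"S = {smap.n_segments} <= N = {n_lines}"
            continue
        if include_recipient:
            dosage = np.vstack([dosage, np.zeros((1, n_markers), dtype=np.int8)])
            geno = MarkerGenotypes(
                line_ids=geno.line_ids + [RECIPIENT_ID],
                markers=spec.marker_table(),
                dosage=dosage,
            )
        return geno
    raise RuntimeError(
        f"no admissible overlapping population in {max_tries} draws; "
        f"last failed constraint: {last_fail}"
    )


def _genetic_values(geno: MarkerGenotypes, arch: TraitArchitecture) -> np.ndarray:
    g = np.zeros(geno.n_lines)
    for chrom, p, a in arch.loci:
        g = g + a * geno.dosage_at(chrom, p)
    return g


def simulate_trait(
    geno: MarkerGenotypes,
    n_loci: int = 2,
    h2: float = 0.5,
    seed: int | None = None,
    architecture: TraitArchitecture | None = None,
    donor_advantage: float = 100.0,
    n_reps: int = 1,
    rng: np.random.Generator | None = None,
    max_tries: int = 100,
) -> tuple[PhenotypeVector, TraitArchitecture]:
    """Simulate an additive oligogenic trait on an introgression population.

    Causal loci are drawn uniformly over the continuous genome and snapped
    to the nearest marker of their chromosome (the marker panel delimits
    the donor blocks, so a gene between markers is indistinguishable from
    one at the nearest marker); each allele effect is
    ``donor_advantage / (2 * n_loci)``.  The genetic value of a line sums
    the per-locus effects times the line's donor dosage at the locus (0
    where no line carries donor material).  Environmental noise is normal
    with variance ``Vg * (1 - h2) / h2`` on the line-mean scale, where Vg
    is the empirical variance of the genetic values; architectures whose
    loci all fall in uncovered regions (Vg = 0) are redrawn.  A supplied
    zero-effect architecture (global-null calibration) uses unit noise
    variance instead, since the heritability rule is then undefined.

    With ``n_reps > 1``, per-plot values are returned (line-major order,
    line ids repeated) with plot noise variance ``n_reps`` times the
    line-mean variance, so line means retain the target heritability.
    """
    if architecture is not None:
        h2 = architecture.heritability  # the architecture owns the h2
    if not 0 < h2 < 1:
        raise ValueError(f"heritability must be in (0, 1), got {h2}")
    if rng is None:
        rng = np.random.default_rng(seed)
    spec_chroms = geno.chromosomes
    lengths = np.array(
        [geno.marker_positions(c).max() + 0.0 for c in spec_chroms]
    )
    # genome extent per chromosome: up to the last marker plus half a bin
    spacing = np.inf
    for c in spec_chroms:
        p = geno.marker_positions(c)
        if p.size > 1:
            spacing = min(spacing, float(np.min(np.diff(p)[np.diff(p) > 0])))
    if not np.isfinite(spacing):
        spacing = 0.0
    extents = lengths + spacing / 2.0
    total = float(extents.sum())

    if architecture is not None:
        arch = architecture
        g = _genetic_values(geno, arch)
        vg = float(np.var(g))
    else:
        a = donor_advantage / (2.0 * n_loci)
        for _ in range(max_tries):
            loci = []
            for _ in range(n_loci):
                x = rng.uniform(0.0, total)
                ci = int(np.searchsorted(np.cumsum(extents), x, side="right"))
                ci = min(ci, len(spec_chroms) - 1)
                local = x - float(np.concatenate([[0.0], np.cumsum(extents)])[ci])
                chrom = spec_chroms[ci]
                p = geno.marker_positions(chrom)
                snapped = float(p[int(np.argmin(np.abs(p - local)))])
                loci.append((chrom, snapped, a))
            arch = TraitArchitecture(
                loci=loci, heritability=h2, donor_advantage=donor_advantage
            )
            g = _genetic_values(geno, arch)
            vg = float(np.var(g))
            if vg > 0:
                break
        else:
            raise RuntimeError(
                f"no genetically variable architecture found in {max_tries} "
                "draws (all loci fell in uncovered regions)"
            )

    if vg > 0:
        sigma2_mean = vg * (1.0 - h2) / h2
    elif architecture is not None:
        sigma2_mean = 1.0  # null calibration: arbitrary scale
    else:  # pragma: no cover - unreachable, redraw loop guarantees vg > 0
        raise RuntimeError("degenerate architecture with Vg = 0")

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps == 1:
        y = g + rng.normal(0.0, np.sqrt(sigma2_mean), size=g.size)
        ids = list(geno.line_ids)
    else:
        sigma_plot = np.sqrt(n_reps * sigma2_mean)
        y = np.repeat(g, n_reps) + rng.normal(
            0.0, sigma_plot, size=g.size * n_reps
        )
        ids = [l for l in geno.line_ids for _ in range(n_reps)]
    return PhenotypeVector(line_ids=ids, values=y), arch


def classify_detections(
    results: list[SegmentTestResult],
    smap: SegmentMap,
    arch: TraitArchitecture,
) -> tuple[int, int]:
    """Count correctly detected causal loci and false-positive segments.

    A causal locus is correctly detected when at least one significant
    segment's span contains its position (each locus counted at most once);
    every significant segment whose span contains no causal locus counts as
    one false positive.
    """
    by_id = {s.segment_id: s for s in smap.segments}
    sig = [by_id[r.segment_id] for r in results if r.significant]
    n_correct = 0
    for chrom, p, _ in arch.loci:
        if any(seg.contains(chrom, p) for seg in sig):
            n_correct += 1
    n_false = sum(
        1
        for seg in sig
        if not any(seg.contains(chrom, p) for chrom, p, _ in arch.loci)
    )
    return n_correct, n_false


def _n_noncausal(smap: SegmentMap, arch: TraitArchitecture) -> int:
    return sum(
        1
        for seg in smap.segments
        if not any(seg.contains(chrom, p) for chrom, p, _ in arch.loci)
    )


def run_power_experiment(
    population: str | MarkerGenotypes = "ideal",
    methods: tuple[str, ...] = ("LSQ", "BLUP", "RMLV"),
    n_loci: int = 2,
    h2: float = 0.5,
    n_runs: int = 300,
    perm_cfg: PermutationConfig | None = None,
    seed: int = 0,
    n_reps: int = 4,
    include_recipient: bool = True,
    adjust: str = "none",
    donor_advantage: float = 100.0,
    population_seed: int = POPULATION2_SEED,
    spec: GenomeSpec | None = None,
    architecture: TraitArchitecture | None = None,
) -> dict[str, PowerResult]:
    """Monte-Carlo power and false-positive study of the detection pipeline.

    Per run: a fresh random trait architecture and noise draw, one fit and
    one significance test per method at ``perm_cfg.alpha``, and detection
    classification against the causal loci.  ``population`` is ``"ideal"``,
    ``"overlapping"`` or an explicit :class:`MarkerGenotypes`.  LSQ is only
    admissible on the ideal (full-column-rank) population.  Results are
    fully reproducible for a given ``seed``.  Passing a fixed
    ``architecture`` (e.g. one with no causal loci) replaces the per-run
    random architecture — the global-null calibration mode.

    The default desk-scale profile (300 runs, r = 200 permutations,
    unadjusted per-segment p at alpha = 0.01) keeps a three-scenario study
    in the minutes range; the full-scale study (5000 runs, r = 1000) uses
    the same code path.
    """
    spec = spec or GenomeSpec()
    perm_cfg = perm_cfg or PermutationConfig(r=200, alpha=0.01)
    methods = tuple(m.upper() for m in methods)
    for m in methods:
        if m not in ("LSQ", "BLUP", "RMLV"):
            raise ValueError(f"unknown method {m!r}")
    if isinstance(population, MarkerGenotypes):
        geno = population
        pop_name = "custom"
    elif population == "ideal":
        geno = make_ideal_population(spec, include_recipient=include_recipient)
        pop_name = "ideal"
    elif population == "overlapping":
        geno = make_overlapping_population(
            spec, seed=population_seed, include_recipient=include_recipient
        )
        pop_name = "overlapping"
    else:
        raise ValueError(f"unknown population {population!r}")
    smap = build_segments(geno)
    design = build_design_matrix(smap)
    Zline = design.Z
    if "LSQ" in methods:
        from .segments import rank_status

        if rank_status(design).status != "full_column_rank":
            raise ValueError(
                f"LSQ requested on the {pop_name} population whose design "
                "matrix is rank deficient; restrict methods to BLUP/RMLV"
            )
        if Zline.shape[0] * n_reps <= Zline.shape[1]:
            raise ValueError(
                "LSQ testing needs more observations than segments; "
                "increase n_reps"
            )
    Zexp = np.repeat(Zline, n_reps, axis=0) if n_reps > 1 else Zline

    if architecture is not None:
        n_loci = architecture.n_loci
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)
    counts = {m: [0, 0, 0] for m in methods}  # correct, false, noncausal
    records = {m: [] for m in methods}
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm_seed = int(child.generate_state(1, np.uint32)[0])
        y, arch = simulate_trait(
            geno,
            n_loci=n_loci,
            h2=h2,
            rng=rng,
            architecture=architecture,
            donor_advantage=donor_advantage,
            n_reps=n_reps,
        )
        yv = y.values
        noncausal = _n_noncausal(smap, arch)
        for m in methods:
            if m == "LSQ":
                mfit = fit_lsq(Zexp, yv)
                results = test_lsq(
                    mfit, Zexp, yv, alpha=perm_cfg.alpha, adjust=adjust
                )
            else:
                mfit = fit_blup(Zexp, yv) if m == "BLUP" else fit_rmlv(Zexp, yv)
                cfg = dataclasses.replace(perm_cfg, seed=perm_seed)
                results = permutation_test(
                    Zexp, yv, method=m, cfg=cfg, fit=mfit, adjust=adjust
                )
            results = [
                dataclasses.replace(r, segment_id=sid)
                for r, sid in zip(results, smap.segment_ids)
            ]
            n_correct, n_false = classify_detections(results, smap, arch)
            counts[m][0] += n_correct
            counts[m][1] += n_false
            counts[m][2] += noncausal
            records[m].append((n_correct, n_false, noncausal))
        if (run + 1) % 50 == 0:
            logger.info(
                "power experiment %s: %d/%d runs", pop_name, run + 1, n_runs
            )
    return {
        m: PowerResult(
            method=m,
            n_runs=n_runs,
            n_loci=n_loci,
            correctly_detected_sum=counts[m][0],
            false_positive_sum=counts[m][1],
            n_noncausal_total=counts[m][2],
            per_run=records[m],
        )
        for m in methods
    }


@dataclasses.dataclass
class WorkedExample:
    """Deterministic single-gene demonstration data set."""

    genotypes: MarkerGenotypes
    segment_map: SegmentMap
    design: DesignMatrix  # plot-level (rows repeated per replicate)
    phenotypes: PhenotypeVector  # plot values
    architecture: TraitArchitecture
    causal_segment_id: str
    n_reps: int


def worked_example(
    population: int = 1,
    seed: int = 0,
    effect: float = 0.5,
    h2: float = 0.9,
    n_reps: int = 4,
) -> WorkedExample:
    """Single-major-gene worked example on either hypothetical population.

    One causal gene with additive allele effect ``effect`` sits in the
    middle of chromosome 1 (population 2: the most-shared chromosome-1
    segment, at its span midpoint).  Phenotypes are ``n_reps`` replicated
    plot values per line, recipient checks included, at line-mean
    heritability ``h2``.
    """
    spec = GenomeSpec()
    if population == 1:
        geno = make_ideal_population(spec, include_recipient=True)
    elif population == 2:
        geno = make_overlapping_population(spec, include_recipient=True)
    else:
        raise ValueError("population must be 1 or 2")
    smap = build_segments(geno)
    center = spec.chromosome_length_cM / 2.0
    chr1 = spec.chromosome_ids[0]
    candidates = [s for s in smap.segments if s.chromosome == chr1]
    if population == 1:
        causal = min(
            candidates,
            key=lambda s: abs((s.start_cM + s.end_cM) / 2.0 - center),
        )
        locus_pos = center
        if not causal.contains(chr1, locus_pos):
            locus_pos = (causal.start_cM + causal.end_cM) / 2.0
    else:
        causal = max(
            candidates,
            key=lambda s: (
                s.carrier_count,
                -abs((s.start_cM + s.end_cM) / 2.0 - center),
            ),
        )
        locus_pos = (causal.start_cM + causal.end_cM) / 2.0
    arch = TraitArchitecture(
        loci=[(chr1, locus_pos, effect)],
        heritability=h2,
        donor_advantage=2.0 * effect,
    )
    y, arch = simulate_trait(
        geno, h2=h2, seed=seed, architecture=arch, n_reps=n_reps
    )
    design = build_design_matrix(smap).expand(y.line_ids)
    return WorkedExample(
        genotypes=geno,
        segment_map=smap,
        design=design,
        phenotypes=y,
        architecture=arch,
        causal_segment_id=causal.segment_id,
        n_reps=n_reps,
    )
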