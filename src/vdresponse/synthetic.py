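"""Synthetic cohorts, expression matrices, and genomic sequences.

The generator emulates the statistical structure of a small paired
supplementation trial: 8 subjects sampled at baseline and after 8 weeks
on one of two daily vitamin D3 doses (400 or 2000 IU), with baseline
serum 25(OH)D splitting the cohort into 4 deficient (<20 ng/ml) and 4
insufficient/sufficient subjects.  Expression is simulated directly at
gene level on the log2 scale: a global-null background plus planted
supplementation-responsive effects (follow-up shift in all subjects)
and planted status-dependent effects (baseline shift in the deficient
group).  Genomic sequences carry planted 15-nt VDREs at exact
TSS-relative offsets, while excluded (housekeeping negative control)
windows are iteratively re-sampled until they contain no candidate
site at all.

All randomness flows from one integer seed, split into named
substreams (cohort / expression / sequence) so stages are individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import log2

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import classify_status
from .matrix import ExpressionMatrix
from .vdre import (
    SITE_LEN,
    KnownVdreLibrary,
    ScanEngine,
    ScanParams,
    VdreMotif,
    _position_to_offset,
    decode_bases,
    encode_bases,
    format_site,
    parse_vdre_sequence,
    revcomp,
)

MIN_PLANTED_LOG2FC = log2(1.5)

_STREAMS = ("cohort", "expression", "sequence")


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one seed."""
    if name not in _STREAMS:
        raise ValueError(f"unknown stream {name!r}; valid: {_STREAMS}")
    ss = np.random.SeedSequence([int(seed), _STREAMS.index(name)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRecord:
    """One subject: dose arm, visit-wise serum 25(OH)D, status class."""

    subject_id: str
    sex: str
    age: float
    dose: int
    serum_baseline: float
    serum_followup: float
    status: str

    def __post_init__(self) -> None:
        if self.serum_baseline <= 0 or self.serum_followup <= 0:
            raise ValueError("serum values must be positive")
        expected = classify_status(self.serum_baseline)
        if self.status != expected:
            raise ValueError(
                f"status {self.status!r} inconsistent with baseline "
                f"{self.serum_baseline} ng/ml (expected {expected!r})"
            )


@dataclass(frozen=True)
class ArmSerumParams:
    """Per-arm serum 25(OH)D distribution: baseline and mean increase."""

    baseline_mean: float
    baseline_sd: float
    increase_mean: float
    increase_sd: float = 4.9

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.increase_sd < 0:
            raise ValueError("serum SDs must be non-negative")
        if self.baseline_mean <= 0:
            raise ValueError("baseline mean must be positive")


#: Arm-level serum parameters matching the study demographics table
#: (400 IU: 18.3±1.1 -> 24.0; 2000 IU: 24.0±10.7 -> 33.8 ng/ml).
DEFAULT_SERUM_PARAMS = {
    400: ArmSerumParams(18.3, 1.1, 5.7, 4.9),
    2000: ArmSerumParams(24.0, 10.7, 9.8, 4.9),
}

_WOMEN_FRACTION = {400: 2 / 3, 2000: 1 / 5}
_AGE = {400: (27.3, 2.0), 2000: (26.0, 5.1)}


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        out = np.full(size if size else 1, float(mean))
        return out if size else float(out[0])
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draw = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size or 1,
                               random_state=rng)
    return draw if size else float(draw[0])


def gen_cohort(
    n_400: int,
    n_2000: int,
    serum_params: dict[int, ArmSerumParams] | None = None,
    seed: int = 0,
) -> list[CohortRecord]:
    """Simulate a two-arm cohort with arm-level serum parameters.

    Baseline serum is normal per arm, the follow-up value adds a
    normal increase; status follows the 20 ng/ml deficiency rule.
    """
    if n_400 < 1 or n_2000 < 1:
        raise ValueError("both arms need at least one subject")
    params = serum_params or DEFAULT_SERUM_PARAMS
    rng = substream_rng(seed, "cohort")
    records: list[CohortRecord] = []
    idx = 0
    for dose, n in ((400, n_400), (2000, n_2000)):
        arm = params[dose]
        for _ in range(n):
            idx += 1
            baseline = _truncnorm(rng, arm.baseline_mean, arm.baseline_sd, 1.0, 80.0)
            increase = float(rng.normal(arm.increase_mean, arm.increase_sd)) \
                if arm.increase_sd > 0 else arm.increase_mean
            followup = max(baseline + increase, 1.0)
            sex = "F" if rng.random() < _WOMEN_FRACTION[dose] else "M"
            age = _truncnorm(rng, *_AGE[dose], 18.0, 65.0)
            records.append(
                CohortRecord(
                    subject_id=f"S{idx:02d}",
                    sex=sex,
                    age=round(age, 1),
                    dose=dose,
                    serum_baseline=round(baseline, 1),
                    serum_followup=round(followup, 1),
                    status=classify_status(round(baseline, 1)),
                )
            )
    return records


def default_study_cohort(seed: int = 0) -> list[CohortRecord]:
    """The study-structured cohort: 3+5 dose arms, 4v4 status split.

    Serum baselines are drawn from truncated normals per status group
    (deficient 16±3.8 ng/ml on [10, 19.5]; insufficient/sufficient
    27.6±5.4 on [20.5, 40]) so the 4-deficient / 4-other baseline
    structure needed by the status contrast always holds.  The three
    400 IU subjects and one 2000 IU subject are deficient.
    """
    rng = substream_rng(seed, "cohort")
    layout = [
        ("S01", 400, "deficient"),
        ("S02", 400, "deficient"),
        ("S03", 400, "deficient"),
        ("S04", 2000, "deficient"),
        ("S05", 2000, "insufficient_sufficient"),
        ("S06", 2000, "insufficient_sufficient"),
        ("S07", 2000, "insufficient_sufficient"),
        ("S08", 2000, "insufficient_sufficient"),
    ]
    records = []
    for subject, dose, status in layout:
        if status == "deficient":
            baseline = _truncnorm(rng, 16.0, 3.8, 10.0, 19.5)
        else:
            baseline = _truncnorm(rng, 27.6, 5.4, 20.5, 40.0)
        arm = DEFAULT_SERUM_PARAMS[dose]
        increase = _truncnorm(rng, arm.increase_mean, arm.increase_sd, 0.5, 25.0)
        sex = "F" if rng.random() < _WOMEN_FRACTION[dose] else "M"
        age = _truncnorm(rng, *_AGE[dose], 18.0, 65.0)
        records.append(
            CohortRecord(
                subject_id=subject,
                sex=sex,
                age=round(age, 1),
                dose=dose,
                serum_baseline=round(baseline, 1),
                serum_followup=round(baseline + increase, 1),
                status=status,
            )
        )
    return records


def cohort_frame(cohort: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in cohort]).set_index("subject_id")


# ---------------------------------------------------------------------------
# truth designs and expression generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGene:
    """A gene with a planted signed log2 effect."""

    gene_id: str
    direction: str  # up | down
    log2fc: float  # magnitude, > 0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.log2fc < MIN_PLANTED_LOG2FC:
            raise ValueError(
                f"planted |log2FC| must be >= log2(1.5) = {MIN_PLANTED_LOG2FC:.3f}, "
                f"got {self.log2fc} for {self.gene_id}"
            )

    @property
    def signed(self) -> float:
        return self.log2fc if self.direction == "up" else -self.log2fc


@dataclass
class TruthDesign:
    """Simulation truth: planted responsive and status-dependent genes.

    ``responsive`` genes shift follow-up vs baseline in every subject;
    ``status_dependent`` genes shift the deficient group's baseline
    (direction = effect in the deficient group).  A gene may appear in
    both lists only when named in ``declared_overlap``.
    """

    n_genes: int
    responsive: list[PlantedGene] = field(default_factory=list)
    status_dependent: list[PlantedGene] = field(default_factory=list)
    residual_sd: float = 0.1
    seed: int = 0
    declared_overlap: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        overlap = {g.gene_id for g in self.responsive} & {
            g.gene_id for g in self.status_dependent
        }
        undeclared = overlap - self.declared_overlap
        if undeclared:
            raise ValueError(
                f"genes planted in both lists without declaration: "
                f"{sorted(undeclared)[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


def _draw_planted(rng, universe, n_up, n_down, lo, hi) -> list[PlantedGene]:
    chosen = rng.choice(len(universe), size=n_up + n_down, replace=False)
    mags = rng.uniform(lo, hi, size=n_up + n_down)
    out = []
    for k, (idx, mag) in enumerate(zip(chosen, mags)):
        direction = "up" if k < n_up else "down"
        out.append(PlantedGene(universe[idx], direction, float(mag)))
    return out


def default_supplementation_design(
    seed: int = 0,
    n_genes: int = 20_000,
    n_up: int = 209,
    n_down: int = 82,
    effect_range: tuple[float, float] = (0.7, 4.7),
    residual_sd: float = 0.1,
) -> TruthDesign:
    """Truth design emulating the supplementation-responsive gene list.

    One planted responsive gene per reported list entry: 209 up, 82
    down by default, |log2FC| uniform on [0.7, 4.7] (strictly above the
    1.5-fold boundary of 0.585 so threshold flicker cannot change the
    recovered counts at the default residual SD of 0.1).
    """
    rng = substream_rng(seed, "expression")
    universe = [f"G{i + 1:05d}" for i in range(n_genes)]
    planted = _draw_planted(rng, universe, n_up, n_down, *effect_range)
    return TruthDesign(
        n_genes=n_genes, responsive=planted, residual_sd=residual_sd, seed=seed
    )


def default_status_design(
    seed: int = 0,
    n_genes: int = 20_000,
    n_up: int = 14,
    n_down: int = 52,
    effect_range: tuple[float, float] = (1.0, 4.7),
    residual_sd: float = 0.1,
) -> TruthDesign:
    """Truth design emulating the baseline status-dependent gene set.

    14 genes up and 52 down in the deficient group at baseline,
    |log2FC| uniform on [1.0, 4.7].
    """
    rng = substream_rng(seed, "expression")
    universe = [f"G{i + 1:05d}" for i in range(n_genes)]
    planted = _draw_planted(rng, universe, n_up, n_down, *effect_range)
    return TruthDesign(
        n_genes=n_genes, status_dependent=planted, residual_sd=residual_sd, seed=seed
    )


def gen_expression(
    cohort: list[CohortRecord], truth: TruthDesign
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a log2 expression matrix with planted effects.

    One column per (subject, visit).  Returns the matrix and a truth
    table (per planted gene: kind, direction, planted log2FC) for
    recovery scoring.  With ``residual_sd = 0`` the planted paired
    log2 fold changes are exactly recoverable.
    """
    genes = truth.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    for planted in (*truth.responsive, *truth.status_dependent):
        if planted.gene_id not in gene_index:
            raise ValueError(f"planted gene {planted.gene_id!r} not in universe")
    # noise stream is a child of the expression stream so it stays
    # decoupled from the draws the design constructors consumed
    rng = np.random.default_rng(
        np.random.SeedSequence([int(truth.seed), _STREAMS.index("expression"), 1])
    )

    sample_ids, meta_rows = [], []
    for rec in cohort:
        for visit in ("baseline", "followup"):
            sid = f"{rec.subject_id}_{visit}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject": rec.subject_id,
                    "visit": visit,
                    "dose": rec.dose,
                    "status": rec.status,
                    "serum_25ohd": rec.serum_baseline
                    if visit == "baseline"
                    else rec.serum_followup,
                }
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    n_g, n_s = truth.n_genes, len(sample_ids)
    # Intensity background emulating a real array's distribution: a
    # bell-shaped bulk with fat uniform shoulders (dense everywhere a
    # planted effect can move a gene), plus small bright and dim
    # invariant fractions emulating constitutive control features
    # (rRNA, actin-class probes) and the background-level noise floor.
    # Quantile normalization is rank-preserving, so wherever planted
    # mass lands the local density must be high enough that null genes
    # are not displaced by more than a small fraction of the 1.5-fold
    # selection boundary; the invariant pads extend past the maximum
    # reach of any planted effect so no planted gene can occupy the
    # global rank extremes.
    is_shoulder = rng.random(n_g) < 0.35
    base_level = np.where(
        is_shoulder,
        rng.uniform(4.5, 15.0, size=n_g),
        rng.normal(9.0, 1.2, size=n_g),
    )
    planted_idx = {
        gene_index[p.gene_id]
        for p in (*truth.responsive, *truth.status_dependent)
    }
    null_idx = np.array(
        [i for i in range(n_g) if i not in planted_idx], dtype=int
    )
    n_tail = min(int(0.02 * n_g), len(null_idx) // 2)
    if n_tail:
        tail_pick = rng.choice(null_idx, size=2 * n_tail, replace=False)
        base_level[tail_pick[:n_tail]] = rng.uniform(15.0, 19.8, size=n_tail)
        base_level[tail_pick[n_tail:]] = rng.uniform(0.2, 4.5, size=n_tail)
    values = np.tile(base_level[:, None], (1, n_s))
    if truth.residual_sd > 0:
        values = values + rng.normal(0.0, truth.residual_sd, size=(n_g, n_s))

    is_followup = np.array([m["visit"] == "followup" for m in meta_rows])
    is_def_base = np.array(
        [m["visit"] == "baseline" and m["status"] == "deficient" for m in meta_rows]
    )
    for planted in truth.responsive:
        values[gene_index[planted.gene_id], is_followup] += planted.signed
    for planted in truth.status_dependent:
        values[gene_index[planted.gene_id], is_def_base] += planted.signed

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), meta
    )
    truth_rows = [
        {"gene_id": p.gene_id, "kind": kind, "direction": p.direction,
         "planted_log2fc": p.log2fc}
        for kind, plist in (
            ("responsive", truth.responsive),
            ("status", truth.status_dependent),
        )
        for p in plist
    ]
    truth_table = pd.DataFrame(
        truth_rows, columns=["gene_id", "kind", "direction", "planted_log2fc"]
    )
    return matrix, truth_table


# ---------------------------------------------------------------------------
# sequence generation with planted / excluded VDREs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TssAnnotation:
    """TSS of a gene within a named sequence (1-based, gene strand)."""

    gene_id: str
    seq_id: str
    tss_position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if self.tss_position < 1:
            raise ValueError("tss_position is 1-based and must be >= 1")


@dataclass
class SequenceSet:
    """Named nucleotide sequences plus TSS annotations."""

    records: dict[str, str]
    annotations: list[TssAnnotation]

    def __post_init__(self) -> None:
        for ann in self.annotations:
            if ann.seq_id not in self.records:
                raise ValueError(f"annotation {ann.gene_id} references missing "
                                 f"sequence {ann.seq_id!r}")
            if ann.tss_position > len(self.records[ann.seq_id]):
                raise ValueError(
                    f"TSS of {ann.gene_id} ({ann.tss_position}) beyond sequence "
                    f"length {len(self.records[ann.seq_id])}"
                )


def make_window_annotations(
    genes: list[tuple[str, str]], window: tuple[int, int] = (150_000, 10_000)
) -> tuple[list[TssAnnotation], dict[str, int]]:
    """One sequence per gene spanning a TSS-relative window.

    ``genes`` is a list of (gene_id, strand).  Returns annotations and
    the sequence lengths; for '+' genes the TSS sits at upstream+1,
    for '-' genes at position downstream (upstream bases above it).
    """
    up, down = window
    down_span = max(down, 1)  # keep >=1 transcribed base so the TSS exists
    anns, lengths = [], {}
    for gene_id, strand in genes:
        seq_id = f"{gene_id}_region"
        length = up + down_span
        tss = up + 1 if strand == "+" else down_span
        anns.append(TssAnnotation(gene_id, seq_id, tss, strand))
        lengths[seq_id] = length
    return anns, lengths


@dataclass(frozen=True)
class PlantedVdre:
    """A 15-nt VDRE instance planted at a TSS-relative offset."""

    gene_id: str
    offset: int  # signed TSS-relative position of the gene-strand 5' end
    motif: str  # 15 nt, UPPER-lower-UPPER

    def __post_init__(self) -> None:
        parse_vdre_sequence(self.motif)


def gen_sequences(
    annotations: list[TssAnnotation],
    seq_lengths: dict[str, int],
    library: KnownVdreLibrary,
    planted: list[PlantedVdre] = (),
    exclude: list[str] = (),
    seed: int = 0,
    motifs: list[VdreMotif] | None = None,
    params: ScanParams | None = None,
    max_scrub_iter: int = 500,
) -> tuple[SequenceSet, pd.DataFrame]:
    """Generate uniform-random sequences with planted/excluded VDREs.

    Background composition is uniform (25% each base).  Every window is
    first scrubbed: qualifying 15-mers are re-drawn iteratively until
    the scanner finds nothing, which guarantees the zero-hit
    postcondition for ``exclude`` genes and makes planted hits the only
    hits anywhere.  Planted motifs are then inserted at their exact
    TSS-relative offsets (reverse-complemented on '-' genes) and any
    spurious junction-induced site is scrubbed around them.

    Returns the sequence set and a truth-hit table
    (gene_id, position, sequence).
    """
    engine = ScanEngine(library, motifs, params)
    ann_by_gene = {a.gene_id: a for a in annotations}
    excluded = set(exclude)
    for p in planted:
        if p.gene_id in excluded:
            raise ValueError(
                f"planted motif for {p.gene_id!r} collides with exclude list"
            )
        if p.gene_id not in ann_by_gene:
            raise ValueError(f"planted gene {p.gene_id!r} has no annotation")
    unknown = [g for g in excluded if g not in ann_by_gene]
    if unknown:
        raise ValueError(f"excluded genes without annotation: {unknown}")

    rng = substream_rng(seed, "sequence")
    planted_by_seq: dict[str, list[tuple[int, str]]] = {}
    for p in planted:
        ann = ann_by_gene[p.gene_id]
        off = _position_to_offset(p.offset, ann.tss_position, ann.strand)
        length = seq_lengths[ann.seq_id]
        if off < 0 or off + SITE_LEN > length:
            raise ValueError(
                f"planted offset {p.offset} for {p.gene_id} falls outside its "
                f"{length}-nt window"
            )
        insert = p.motif.upper() if ann.strand == "+" else revcomp(p.motif.upper())
        site_codes = encode_bases(insert)
        if not engine.qualifying_offsets(site_codes)[0].size:
            raise ValueError(
                f"planted motif {p.motif!r} would not be detected by the "
                "scanner under the given library/parameters"
            )
        planted_by_seq.setdefault(ann.seq_id, []).append((off, insert))

    records: dict[str, str] = {}
    for ann in annotations:
        if ann.seq_id in records:
            continue
        length = seq_lengths[ann.seq_id]
        codes = rng.integers(0, 4, size=length, dtype=np.int8)
        keep = np.zeros(length, dtype=bool)
        allowed: set[int] = set()
        for off, insert in planted_by_seq.get(ann.seq_id, []):
            codes[off : off + SITE_LEN] = encode_bases(insert)
            keep[off : off + SITE_LEN] = True
            allowed.add(off)
        for it in range(max_scrub_iter):
            offsets, _, _ = engine.qualifying_offsets(codes)
            spurious = [o for o in offsets.tolist() if o not in allowed]
            if not spurious:
                break
            redraw: list[int] = []
            for o in spurious:
                for k in range(o, o + SITE_LEN):
                    if not keep[k]:
                        redraw.append(k)
            if not redraw:
                raise RuntimeError(
                    f"cannot scrub a spurious site fully inside planted bases "
                    f"of {ann.seq_id}"
                )
            idx = np.array(sorted(set(redraw)))
            codes[idx] = rng.integers(0, 4, size=len(idx), dtype=np.int8)
        else:
            raise RuntimeError(
                f"scrubbing of {ann.seq_id} did not converge in "
                f"{max_scrub_iter} iterations"
            )
        records[ann.seq_id] = decode_bases(codes)

    seqset = SequenceSet(records, list(annotations))

    # postcondition check, every run: excluded windows are hit-free
    for gene in excluded:
        ann = ann_by_gene[gene]
        codes = encode_bases(records[ann.seq_id])
        if engine.qualifying_offsets(codes)[0].size:
            raise RuntimeError(f"excluded gene {gene} still has candidate sites")

    truth_rows = [
        {"gene_id": p.gene_id, "position": p.offset,
         "sequence": format_site(p.motif)}
        for p in planted
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "position", "sequence"])
    return seqset, truth


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "known_vdres": "known_vdres_synthetic.tsv",
    "motif_defs": "motif_defs_synthetic.tsv",
    "housekeeping": "housekeeping_synthetic.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged machine-readable reference table.

    Valid names: table1 (cohort demographics), table2 (the 17
    VDRE-candidate genes with motif sequences and TSS-relative
    positions), known_vdres (half-site library; a synthetic
    reconstruction from canonical vitamin D target genes),
    motif_defs (scanning motif definitions incl. the RGKTSA consensus;
    synthetic reconstruction), housekeeping (12 negative-control
    housekeeping genes; synthetic list).
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURE_FILES)}"
        )
    path = resources.files("vdresponse").joinpath("fixtures", _FIXTURE_FILES[name])
    with resources.as_file(path) as fp:
        return pd.read_csv(fp, sep="\t")
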