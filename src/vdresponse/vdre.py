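"""Degenerate DR3-type vitamin D response element (VDRE) discovery.

A VDRE is modelled as two hexameric half-sites separated by a 3-nt
spacer (direct repeat, DR3), 15 nt in total, bound by the VDR-RXR
heterodimer.  A candidate site is a 15-mer whose two half-sites each
resemble a known VDRE half-site -- exactly ("identical") or within a
small Hamming distance in either orientation ("similar") -- or whose
half-sites both fit the field consensus RGKTSA (R=A/G, K=G/T, S=C/G).

Scanning reports TSS-relative positions: negative offsets are upstream
of the transcription start site in gene orientation, the first
transcribed base is +1 (there is no position 0).  Because half-site
matching is orientation-agnostic, a 15-mer that qualifies in its
forward reading almost always also qualifies in reverse; each position
is therefore reported once, on the '+' strand when the forward reading
qualifies and on '-' only when solely the reverse complement does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HALF_LEN = 6
SPACER_LEN = 3
SITE_LEN = 2 * HALF_LEN + SPACER_LEN  # 15

CONSENSUS_HALF = "RGKTSA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    """Reverse complement, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _check_hexamer(seq: str, what: str = "half-site") -> str:
    seq = seq.upper()
    if len(seq) != HALF_LEN or any(c not in "ACGT" for c in seq):
        raise ValueError(f"{what} must be 6 nt over A/C/G/T, got {seq!r}")
    return seq


def parse_vdre_sequence(text: str) -> tuple[str, str, str]:
    """Split a printed 15-nt VDRE (UPPER-lower-UPPER) into its parts.

    Half-sites are upper case, the 3-nt spacer lower case, e.g.
    ``GGTTCAagcAGTTCT`` -> ("GGTTCA", "agc", "AGTTCT").
    """
    if len(text) != SITE_LEN:
        raise ValueError(f"VDRE string must be {SITE_LEN} nt, got {text!r}")
    half1, spacer, half2 = text[:6], text[6:9], text[9:]
    if not (half1.isupper() and half2.isupper() and spacer.islower()):
        raise ValueError(
            f"expected UPPER(6)+lower(3)+UPPER(6) case pattern, got {text!r}"
        )
    _check_hexamer(half1)
    _check_hexamer(half2)
    if any(c not in "acgt" for c in spacer):
        raise ValueError(f"spacer must be 3 nt over a/c/g/t, got {spacer!r}")
    return half1, spacer, half2


def format_site(site15: str) -> str:
    """Render a 15-mer with its spacer lowercased."""
    s = site15.upper()
    return s[:6] + s[6:9].lower() + s[9:]


# ---------------------------------------------------------------------------
# motif model and known-VDRE library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VdreMotif:
    """Hexamer + fixed-length spacer + hexamer motif, IUPAC patterns."""

    half1: str
    half2: str
    spacer_len: int = SPACER_LEN
    source: str = "consensus"

    def __post_init__(self) -> None:
        for half in (self.half1, self.half2):
            if len(half) != HALF_LEN or any(c not in IUPAC for c in half.upper()):
                raise ValueError(
                    f"motif half must be 6 IUPAC letters, got {half!r}"
                )
        if self.spacer_len != SPACER_LEN:
            raise ValueError(
                f"only DR{SPACER_LEN} (spacer {SPACER_LEN}) is supported, "
                f"got spacer {self.spacer_len}"
            )

    @property
    def length(self) -> int:
        return 2 * HALF_LEN + self.spacer_len


CONSENSUS_MOTIF = VdreMotif(CONSENSUS_HALF, CONSENSUS_HALF, source="consensus")


@dataclass(frozen=True)
class KnownVdre:
    """One reported VDRE: source gene label, half-sites, optional 15-mer."""

    source: str
    half_sites: tuple[str, ...]
    full_sequence: str | None = None


@dataclass
class KnownVdreLibrary:
    """Collection of reported VDRE half-sites from known target genes."""

    entries: list[KnownVdre] = field(default_factory=list)

    def half_site_pairs(self) -> list[tuple[str, str]]:
        """(source, hexamer) for every half-site, both orientations."""
        out = []
        for e in self.entries:
            for h in e.half_sites:
                out.append((e.source, h))
                out.append((e.source, revcomp(h)))
        return out

    @property
    def sources(self) -> list[str]:
        return [e.source for e in self.entries]


def build_motif_library(
    known_vdres: pd.DataFrame | None,
    motif_defs: pd.DataFrame | None = None,
) -> tuple[KnownVdreLibrary, list[VdreMotif]]:
    """Assemble the known-VDRE half-site library and the motif set.

    ``known_vdres`` needs columns source/half1/half2 (and optionally
    full_sequence); ``motif_defs`` columns name/half1/spacer_len/half2.
    The RGKTSA consensus motif is always included.
    """
    entries: list[KnownVdre] = []
    if known_vdres is not None and len(known_vdres):
        for _, row in known_vdres.iterrows():
            halves = tuple(
                _check_hexamer(str(row[c]), f"half-site of {row['source']!r}")
                for c in ("half1", "half2")
            )
            full = row.get("full_sequence")
            full = None if pd.isna(full) else str(full)
            entries.append(KnownVdre(str(row["source"]), halves, full))
    motifs: list[VdreMotif] = []
    if motif_defs is not None and len(motif_defs):
        for _, row in motif_defs.iterrows():
            motifs.append(
                VdreMotif(
                    str(row["half1"]).upper(),
                    str(row["half2"]).upper(),
                    int(row.get("spacer_len", SPACER_LEN)),
                    source=str(row["name"]),
                )
            )
    if not any(
        m.half1 == CONSENSUS_HALF and m.half2 == CONSENSUS_HALF for m in motifs
    ):
        motifs.append(CONSENSUS_MOTIF)
    return KnownVdreLibrary(entries), motifs


IDENTICAL = "identical"
SIMILAR = "similar"


@dataclass(frozen=True)
class HalfSiteMatch:
    source: str
    klass: str  # identical | similar


def match_half_site(
    hexamer: str, library: KnownVdreLibrary, max_mismatch: int = 1
) -> list[HalfSiteMatch]:
    """Match a hexamer against the library in either orientation.

    Identical = exact equality with a half-site or its reverse
    complement; similar = Hamming distance <= ``max_mismatch``.  One
    match per source, keeping the best class.
    """
    hexamer = _check_hexamer(hexamer, "query hexamer")
    best: dict[str, int] = {}
    for source, site in library.half_site_pairs():
        d = hamming(hexamer, site)
        if d <= max_mismatch and d < best.get(source, max_mismatch + 1):
            best[source] = d
    return [
        HalfSiteMatch(src, IDENTICAL if d == 0 else SIMILAR)
        for src, d in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# fast scanning engine
# ---------------------------------------------------------------------------

def encode_bases(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; anything but ACGT -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, c in _BASE_TO_CODE.items():
        table[ord(b)] = c
        table[ord(b.lower())] = c
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[c] for c in codes)


def _hexamer_digit_table() -> np.ndarray:
    """Digits (base 4, most significant first) of all 4096 hexamers."""
    codes = np.arange(4096)
    return np.stack(
        [(codes >> (2 * (HALF_LEN - 1 - k))) & 3 for k in range(HALF_LEN)], axis=1
    )


_DIGITS = _hexamer_digit_table()
_RC_CODE = (
    np.sum((3 - _DIGITS[:, ::-1]) << (2 * np.arange(HALF_LEN - 1, -1, -1)), axis=1)
)


def _pattern_table(pattern: str) -> np.ndarray:
    """Boolean table over all 4096 hexamers matching an IUPAC pattern."""
    ok = np.ones(4096, dtype=bool)
    for k, letter in enumerate(pattern.upper()):
        allowed = [_BASE_TO_CODE[b] for b in IUPAC[letter]]
        ok &= np.isin(_DIGITS[:, k], allowed)
    return ok


def _site_code(hexamer: str) -> int:
    code = 0
    for ch in hexamer:
        code = (code << 2) | _BASE_TO_CODE[ch]
    return code


@dataclass
class ScanParams:
    """Scanner tuning: mismatch budget and consensus usage."""

    max_mismatch: int = 1
    use_consensus: bool = True


class ScanEngine:
    """Precomputed lookup tables for vectorized DR3 scanning.

    Qualification of a 15-mer: both hexamer half-sites within
    ``max_mismatch`` of some library half-site (either orientation), or
    the (half1, half2) pair fitting one of the IUPAC motifs.
    """

    def __init__(
        self,
        library: KnownVdreLibrary,
        motifs: list[VdreMotif] | None = None,
        params: ScanParams | None = None,
    ) -> None:
        self.library = library
        self.params = params or ScanParams()
        motifs = list(motifs) if motifs is not None else [CONSENSUS_MOTIF]
        if not self.params.use_consensus:
            motifs = [m for m in motifs if m.source != "consensus"]
        self.motifs = motifs

        lib_ok = np.zeros(4096, dtype=bool)
        for _, site in library.half_site_pairs():
            digits = np.array([_BASE_TO_CODE[c] for c in site])
            dist = np.sum(_DIGITS != digits[None, :], axis=1)
            lib_ok |= dist <= self.params.max_mismatch
        self._lib_ok = lib_ok
        self._motif_tables = [
            (_pattern_table(m.half1), _pattern_table(m.half2)) for m in motifs
        ]

    # -- code-level qualification (used by scanning and scrubbing) ----------

    def _pair_qual(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        q = self._lib_ok[h1] & self._lib_ok[h2]
        for a, b in self._motif_tables:
            q |= a[h1] & b[h2]
        return q

    def qualifying_offsets(
        self, codes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(offsets, forward_qual, reverse_qual) over a coded sequence.

        Offsets are 0-based starts of qualifying 15-mers on either
        strand; the boolean arrays say which orientation qualified.
        """
        L = len(codes)
        if L < SITE_LEN:
            empty = np.empty(0, dtype=int)
            return empty, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
        valid = codes >= 0
        clipped = np.where(valid, codes, 0).astype(np.int64)
        hexes = np.zeros(L - HALF_LEN + 1, dtype=np.int64)
        hex_ok = np.ones(L - HALF_LEN + 1, dtype=bool)
        for k in range(HALF_LEN):
            hexes = (hexes << 2) | clipped[k : L - HALF_LEN + 1 + k]
            hex_ok &= valid[k : L - HALF_LEN + 1 + k]
        n = L - SITE_LEN + 1
        h1 = hexes[:n]
        h2 = hexes[HALF_LEN + SPACER_LEN : HALF_LEN + SPACER_LEN + n]
        ok = hex_ok[:n] & hex_ok[HALF_LEN + SPACER_LEN : HALF_LEN + SPACER_LEN + n]
        qf = self._pair_qual(h1, h2) & ok
        qr = self._pair_qual(_RC_CODE[h2], _RC_CODE[h1]) & ok
        any_q = qf | qr
        offsets = np.nonzero(any_q)[0]
        return offsets, qf[offsets], qr[offsets]

    # -- string-level scanning ---------------------------------------------

    def scan(self, sequence: str) -> list["SequenceHit"]:
        codes = encode_bases(sequence)
        offsets, qf, qr = self.qualifying_offsets(codes)
        hits = []
        for off, fwd, rev in zip(offsets.tolist(), qf.tolist(), qr.tolist()):
            site = sequence[off : off + SITE_LEN].upper()
            strand = "+" if fwd else "-"
            oriented = site if fwd else revcomp(site)
            hits.append(
                SequenceHit(
                    offset=off,
                    strand=strand,
                    sequence=format_site(site),
                    matched_sources=self._describe(oriented),
                    forward_qual=fwd,
                    reverse_qual=rev,
                )
            )
        return hits

    def _describe(self, site15: str) -> dict[str, str]:
        h1, h2 = site15[:6], site15[9:]
        out: dict[str, str] = {}
        m1 = match_half_site(h1, self.library, self.params.max_mismatch)
        m2 = match_half_site(h2, self.library, self.params.max_mismatch)
        if m1 and m2:
            for m in (*m1, *m2):
                prev = out.get(m.source)
                if prev is None or (prev == SIMILAR and m.klass == IDENTICAL):
                    out[m.source] = m.klass
        for motif, (a, b) in zip(self.motifs, self._motif_tables):
            if a[_site_code(h1)] and b[_site_code(h2)]:
                out.setdefault(motif.source, "motif")
        return out


@dataclass
class SequenceHit:
    """A candidate VDRE within a bare sequence (0-based offset)."""

    offset: int
    strand: str
    sequence: str
    matched_sources: dict[str, str]
    forward_qual: bool = True
    reverse_qual: bool = False

    @property
    def sources(self) -> set[str]:
        return set(self.matched_sources)


def scan_sequence(
    sequence: str,
    motifs: list[VdreMotif] | None,
    library: KnownVdreLibrary,
    params: ScanParams | None = None,
) -> list[SequenceHit]:
    """Scan one sequence for candidate VDREs on both strands.

    Hits are reported deterministically left to right; a position whose
    forward reading qualifies is reported on '+', otherwise on '-'.
    ``N`` never matches.  Sequences shorter than 15 nt yield no hits.
    """
    engine = ScanEngine(library, motifs, params)
    return engine.scan(sequence)


# ---------------------------------------------------------------------------
# TSS-relative scanning
# ---------------------------------------------------------------------------

@dataclass
class VdreHit:
    """Candidate VDRE with TSS-relative position in gene orientation."""

    gene_id: str
    position: int  # 5' end of the motif; negative = upstream, no 0
    strand: str  # relative to the gene
    sequence: str  # gene-strand orientation, spacer lowercased
    matched_sources: dict[str, str]

    @property
    def sources(self) -> set[str]:
        return set(self.matched_sources)


def _offset_to_position(offset0: int, tss_1based: int, gene_strand: str) -> int:
    """Signed TSS-relative position of a motif's gene-strand 5' end.

    The first transcribed base is +1; the base immediately upstream is
    -1 (there is no position 0).
    """
    if gene_strand == "+":
        p = offset0 + 1  # 1-based physical start = 5' end
        return p - tss_1based if p < tss_1based else p - tss_1based + 1
    q = offset0 + SITE_LEN  # 1-based physical end = gene-strand 5' end
    return tss_1based - q if q > tss_1based else tss_1based - q + 1


def _position_to_offset(position: int, tss_1based: int, gene_strand: str) -> int:
    """Inverse of :func:`_offset_to_position` (0-based sequence offset)."""
    if position == 0:
        raise ValueError("TSS-relative position 0 does not exist")
    if gene_strand == "+":
        p = tss_1based + position if position < 0 else tss_1based + position - 1
        return p - 1
    q = tss_1based - position if position < 0 else tss_1based - position + 1
    return q - SITE_LEN


def scan_upstream(
    sequences,
    library: KnownVdreLibrary,
    motifs: list[VdreMotif] | None = None,
    window: tuple[int, int] = (150_000, 10_000),
    params: ScanParams | None = None,
    genes: list[str] | None = None,
) -> list[VdreHit]:
    """Scan TSS-relative windows of annotated genes for candidate VDREs.

    ``sequences`` is a :class:`~vdresponse.synthetic.SequenceSet`-like
    object with ``records`` (seq_id -> sequence) and ``annotations``
    (gene_id, seq_id, tss 1-based, strand).  ``window`` is
    (upstream_bp, downstream_bp); hits outside it are dropped.
    """
    up_bp, down_bp = window
    if up_bp < 0 or down_bp < 0:
        raise ValueError("window bounds must be >= 0")
    engine = ScanEngine(library, motifs, params)
    ann_by_gene = {a.gene_id: a for a in sequences.annotations}
    if genes is None:
        targets = [a.gene_id for a in sequences.annotations]
    else:
        missing = [g for g in genes if g not in ann_by_gene]
        if missing:
            raise KeyError(f"genes without TSS annotation: {missing}")
        targets = list(genes)
    hits: list[VdreHit] = []
    for gene in targets:
        ann = ann_by_gene[gene]
        seq = sequences.records[ann.seq_id]
        for shit in engine.scan(seq):
            pos = _offset_to_position(shit.offset, ann.tss_position, ann.strand)
            if not (-up_bp <= pos <= down_bp):
                continue
            site = seq[shit.offset : shit.offset + SITE_LEN].upper()
            if ann.strand == "-":
                site = revcomp(site)
            # strand relative to the gene: '+' when the gene-strand
            # reading of the 15-mer qualifies (both often do, since
            # half-site matching is orientation-agnostic)
            gene_reading_quals = (
                shit.forward_qual if ann.strand == "+" else shit.reverse_qual
            )
            strand = "+" if gene_reading_quals else "-"
            described = site if gene_reading_quals else revcomp(site)
            hits.append(
                VdreHit(
                    gene_id=gene,
                    position=pos,
                    strand=strand,
                    sequence=format_site(site),
                    matched_sources=engine._describe(described),
                )
            )
    hits.sort(key=lambda h: (h.gene_id, h.position))
    return hits


def hits_to_frame(hits: list[VdreHit]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": h.gene_id,
            "position": h.position,
            "strand": h.strand,
            "sequence": h.sequence,
            "matched_sources": ";".join(sorted(h.matched_sources)),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "position", "strand", "sequence", "matched_sources"]
    )


# ---------------------------------------------------------------------------
# positive / negative control evaluation
# ---------------------------------------------------------------------------

@dataclass
class ControlSummary:
    """Detection flags for positives and total hit count in negatives."""

    detected: dict[str, bool]
    sensitivity: float
    negative_hit_count: int


def control_evaluation(
    positive_genes: list[str],
    negative_genes: list[str],
    hits: list[VdreHit],
    annotated_genes: list[str] | None = None,
) -> ControlSummary:
    """Summarize scanner performance on control gene sets.

    Sensitivity is the fraction of positive genes with at least one
    hit; the negative count is the total number of hits in the
    negative (housekeeping) set, expected to be zero.
    """
    if annotated_genes is not None:
        known = set(annotated_genes)
        unknown = [g for g in [*positive_genes, *negative_genes] if g not in known]
        if unknown:
            raise KeyError(f"unknown control gene labels: {unknown}")
    by_gene: dict[str, int] = {}
    for h in hits:
        by_gene[h.gene_id] = by_gene.get(h.gene_id, 0) + 1
    detected = {g: by_gene.get(g, 0) > 0 for g in positive_genes}
    sensitivity = (
        sum(detected.values()) / len(detected) if detected else float("nan")
    )
    negative_count = sum(by_gene.get(g, 0) for g in negative_genes)
    return ControlSummary(detected, sensitivity, negative_count)
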