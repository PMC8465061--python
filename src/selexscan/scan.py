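"""PWM genome scanning with exact p-values and promoter-window annotation.

Every window of the genome (both strands) is scored with a log2-odds matrix.
P-values are exact under the 0-order background model: per-position scores
are discretised to a shared integer grid and the distribution of the total
score of a random background word is computed by position-wise convolution;
the survival function of that distribution gives, for each observed score,
the probability that a random sequence of the same length matches at least
as well.  Window scores are computed on the same integer grid, so DP
p-values agree exactly with brute-force enumeration at the same
discretisation.  Benjamini-Hochberg q-values are assigned over the full
number of tested windows.

Coordinates are 0-based half-open internally and 1-based inclusive in every
emitted hit (GFF/FIMO convention).
"""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pwm import PWMotif
from .seqs import encode, revcomp

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "frame", "attributes",
]


@dataclasses.dataclass
class GenomeHit:
    """One scored, strand-aware motif occurrence (1-based inclusive coords)."""

    sequence_name: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    q_value: float
    matched_sequence: str


@dataclasses.dataclass
class PromoterCall:
    """Promoter-window assignment of a hit relative to a gene start.

    ``offset`` is the hit's position relative to the gene's annotated start
    (translation start as TSS proxy) on the gene's strand; negative is
    upstream.  ``location_class`` is one of ``window`` (within
    -upstream..+downstream), ``intragenic`` or ``intergenic_far``.
    """

    hit: GenomeHit
    gene_id: str | None
    offset: int | None
    location_class: str
    bidirectional: bool = False


def log_odds(
    pwm: PWMotif, background: np.ndarray | None = None, pseudocount: float = 0.01
) -> np.ndarray:
    """Log2-odds scoring matrix: entry(i, b) = log2((p_ib + pc) / bg_b)."""
    return pwm.log_odds(background=background, pseudocount=pseudocount)


class ScoreDistribution:
    """Exact discretised null distribution of PWM scores under a 0-order background.

    The common integer grid uses ``granularity`` bins across the widest
    per-position score range; integer window scores computed with
    ``int_matrix`` can be mapped to p-values via :meth:`pvalue_of_int`.
    """

    def __init__(
        self, score_matrix: np.ndarray, background: np.ndarray, granularity: int = 1000
    ):
        score_matrix = np.asarray(score_matrix, dtype=float)
        if score_matrix.ndim != 2 or score_matrix.shape[1] != 4 or score_matrix.shape[0] < 1:
            raise ValueError("score matrix must have shape (width >= 1, 4)")
        if not np.isfinite(score_matrix).all():
            raise ValueError(
                "score matrix contains non-finite entries; use a pseudocount > 0"
            )
        if granularity < 100:
            raise ValueError("granularity must be >= 100 bins")
        self.background = np.asarray(background, dtype=float)
        self.width = score_matrix.shape[0]
        col_min = score_matrix.min(axis=1)
        col_range = (score_matrix.max(axis=1) - col_min).max()
        self.scale = granularity / col_range if col_range > 0 else 1.0
        self.int_matrix = np.rint((score_matrix - col_min[:, None]) * self.scale).astype(
            np.int64
        )
        self.int_offset = col_min  # per-position float offsets (for reference)
        # Position-wise convolution of per-position integer-score pmfs.
        pmf = np.ones(1)
        for k in range(self.width):
            col_pmf = np.zeros(self.int_matrix[k].max() + 1)
            np.add.at(col_pmf, self.int_matrix[k], self.background)
            pmf = np.convolve(pmf, col_pmf)
        self.pmf = pmf
        # survival[s] = P(integer score >= s)
        self.survival = np.cumsum(pmf[::-1])[::-1]
        self.max_int = len(pmf) - 1

    def int_score(self, window: np.ndarray) -> int:
        """Integer score of one encoded window on the shared grid."""
        return int(self.int_matrix[np.arange(self.width), window].sum())

    def pvalue_of_int(self, int_scores: np.ndarray | int) -> np.ndarray | float:
        s = np.clip(np.asarray(int_scores), 0, self.max_int)
        return self.survival[s]

    def as_mapping(self) -> dict[int, float]:
        """score -> P(score >= s) for every attainable integer score."""
        return {s: float(self.survival[s]) for s in range(self.max_int + 1)}


def _load_sequences(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    if isinstance(genome, (str, Path)) and Path(str(genome)).exists():
        recs = list(SeqIO.parse(str(genome), "fasta"))
        if not recs:
            raise ValueError(f"no sequences in FASTA {genome}")
        return {rec.id: str(rec.seq).upper() for rec in recs}
    if isinstance(genome, str):
        return {"seq": genome.upper()}
    raise TypeError("genome must be a FASTA path, a sequence string, or a name->sequence dict")


def _genome_composition(seqs: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs.values():
        arr = encode(s, strict=False)
        counts += np.bincount(arr[arr >= 0], minlength=4)[:4]
    return counts / counts.sum()


def _window_int_scores(enc: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer scores of all windows of one strand; windows with non-ACGT = -1."""
    w = int_matrix.shape[0]
    n_win = len(enc) - w + 1
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for k in range(w):
        col = enc[k : k + n_win]
        valid &= col >= 0
        scores += int_matrix[k, np.clip(col, 0, 3)]
    scores[~valid] = -1
    return scores


def scan(
    genome,
    pwm: PWMotif,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
    granularity: int = 1000,
) -> list[GenomeHit]:
    """Scan both strands of a genome, reporting every window with p <= threshold.

    The background defaults to the scanned genome's own 0-order composition.
    q-values are Benjamini-Hochberg over all 2 * sum(len - w + 1) tested
    windows.  Hits are sorted by p-value, then coordinate.
    """
    seqs = _load_sequences(genome)
    w = pwm.width
    for name, s in seqs.items():
        if len(s) < w:
            raise ValueError(f"sequence {name!r} shorter than motif width {w}")
    bg = _genome_composition(seqs) if background is None else np.asarray(background, float)
    # Complement-symmetrise the background so the forward null distribution is
    # exact for both strands (a double-stranded scan sees each word and its
    # reverse complement equally often).
    bg = 0.5 * (bg + bg[::-1])
    lom = log_odds(pwm, background=bg, pseudocount=pseudocount)
    lom_rc = lom[::-1, ::-1]
    dist = ScoreDistribution(lom, bg, granularity=granularity)
    im = dist.int_matrix
    im_rc = im[::-1, ::-1]
    raw: list[tuple[float, str, int, str, float]] = []  # (p, name, start0, strand, score)
    n_tests = 0
    for name, s in seqs.items():
        enc = encode(s, strict=False)
        n_win = len(s) - w + 1
        n_tests += 2 * n_win
        fwd = _window_int_scores(enc, im)
        rev = _window_int_scores(enc, im_rc)
        for strand, ints in (("+", fwd), ("-", rev)):
            ok = ints >= 0
            pvals = np.ones(n_win)
            pvals[ok] = dist.pvalue_of_int(ints[ok])
            keep = ok & (pvals <= p_threshold)
            for i in np.flatnonzero(keep):
                window = enc[i : i + w]
                mat = lom if strand == "+" else lom_rc
                score = float(mat[np.arange(w), window].sum())
                raw.append((float(pvals[i]), name, int(i), strand, score))
    raw.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    # Benjamini-Hochberg over all tested windows: q_i = min_{j>=i} p_j * m / rank_j.
    qvals = np.empty(len(raw))
    running = np.inf
    for i in range(len(raw) - 1, -1, -1):
        running = min(running, raw[i][0] * n_tests / (i + 1))
        qvals[i] = min(running, 1.0)
    hits = []
    for (p, name, i, strand, score), q in zip(raw, qvals):
        sub = seqs[name][i : i + w]
        hits.append(
            GenomeHit(
                sequence_name=name,
                start=i + 1,
                end=i + w,
                strand=strand,
                score=score,
                p_value=p,
                q_value=float(q),
                matched_sequence=sub if strand == "+" else revcomp(sub),
            )
        )
    return hits


def hits_to_frame(hits: Iterable[GenomeHit], motif_id: str = "motif_1") -> pd.DataFrame:
    """FIMO-like TSV layout for a list of hits."""
    return pd.DataFrame(
        [
            {
                "motif_id": motif_id,
                "sequence_name": h.sequence_name,
                "start": h.start,
                "stop": h.end,
                "strand": h.strand,
                "score": h.score,
                "p-value": h.p_value,
                "q-value": h.q_value,
                "matched_sequence": h.matched_sequence,
            }
            for h in hits
        ]
    )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read the 9-column GFF3 table, adding a ``gene_id`` column from ID=/Name=."""
    df = pd.read_csv(path, sep="\t", comment="#", names=GFF3_COLUMNS, header=None)
    if df.empty:
        raise ValueError(f"no features in {path}")

    def gene_id(attrs: str) -> str:
        for field in str(attrs).split(";"):
            field = field.strip()
            for key in ("ID=", "Name=", "gene_id="):
                if field.startswith(key):
                    return field[len(key):]
        return attrs

    df["gene_id"] = df["attributes"].map(gene_id)
    return df


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        features[GFF3_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def annotate_hits(
    hits: Sequence[GenomeHit],
    features: pd.DataFrame | str | Path,
    window_upstream: int = 200,
    window_downstream: int = 20,
    far_threshold: float = 5e-6,
) -> list[PromoterCall]:
    """Assign hits (p <= far_threshold) to gene promoter windows.

    A hit is called for every gene whose start (translation start, TSS proxy)
    places the hit within [-window_upstream, +window_downstream] on that
    gene's strand; hits within the windows of two divergent genes yield two
    calls flagged bidirectional.  Hits inside a gene body and in no window
    are ``intragenic``; all remaining hits are ``intergenic_far``.
    """
    if isinstance(features, (str, Path)):
        features = read_gff3(features)
    if (features["end"] < features["start"]).any():
        raise ValueError("feature with end < start")
    genes = features[features["type"].isin(["gene", "CDS", "ORF"])].copy()
    if "gene_id" not in genes.columns:
        genes["gene_id"] = [f"gene_{i}" for i in range(len(genes))]
    calls: list[PromoterCall] = []
    for hit in hits:
        if hit.p_value > far_threshold:
            continue
        same_seq = genes[genes["seqid"] == hit.sequence_name]
        window_rows: list[tuple[str, int, str]] = []  # (gene_id, offset, strand)
        inside: tuple[str, int] | None = None
        for row in same_seq.itertuples():
            if row.strand == "+":
                gene_start = row.start
                offset = hit.start - gene_start
            else:
                gene_start = row.end
                offset = gene_start - hit.end
            if -window_upstream <= offset <= window_downstream:
                window_rows.append((row.gene_id, int(offset), row.strand))
            if row.start <= hit.start and hit.end <= row.end and inside is None:
                inside = (row.gene_id, int(offset))
        if window_rows:
            bidirectional = len({s for _, _, s in window_rows}) == 2
            for gene_id, offset, _ in window_rows:
                calls.append(
                    PromoterCall(
                        hit=hit,
                        gene_id=gene_id,
                        offset=offset,
                        location_class="window",
                        bidirectional=bidirectional,
                    )
                )
        elif inside is not None:
            calls.append(
                PromoterCall(
                    hit=hit, gene_id=inside[0], offset=inside[1], location_class="intragenic"
                )
            )
        else:
            calls.append(
                PromoterCall(hit=hit, gene_id=None, offset=None, location_class="intergenic_far")
            )
    return calls


def calls_to_frame(calls: Iterable[PromoterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_name": c.hit.sequence_name,
                "hit_start": c.hit.start,
                "hit_end": c.hit.end,
                "hit_strand": c.hit.strand,
                "p-value": c.hit.p_value,
                "gene_id": c.gene_id,
                "offset": c.offset,
                "location_class": c.location_class,
                "bidirectional": c.bidirectional,
            }
            for c in calls
        ]
    )
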