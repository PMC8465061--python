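"""Synthetic inputs for every pipeline stage.

The generators emulate a REPSA selection experiment: 73-bp double-stranded
templates carrying a central randomized 24-nt core between defined flanks
that contain type IIS restriction endonuclease (FokI, BpmI) recognition
sites.  Protein occupancy of a core protects the template from cleavage;
survivors are PCR-amplified (multinomial resampling at fixed depth) into the
next round.  Further generators produce sequencing reads with substitution
noise, synthetic genomes with planted sites and a gene table, 1:1 Langmuir
biosensor sensorgrams, and cleavage-protection band intensities.

Every generator takes an explicit seed and is bit-reproducible.
"""
from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import Sensorgram, model_response
from .pwm import IUPAC_MASKS, PWMotif
from .repa import RepaMeasurement
from .seqs import DNA, decode_many, encode, encode_many, revcomp

# Synthetic stand-ins for the selection-template flanks: 25-nt left flank with
# FokI (GGATG) and BpmI (CTGGAG) recognition sites reading into the core,
# 24-nt right flank with both sites on the opposite strand (CTCCAG, CATCC).
# 25 + 24 + 24 = 73 bp total.
LEFT_FLANK = "CCTACGGATGATCCTGGAGGTCGAC"
RIGHT_FLANK = "GTCGACCTCCAGTACATCCGTAAC"
CORE_LENGTH = 24
TEMPLATE_LENGTH = 73


@dataclasses.dataclass(frozen=True)
class SelectionTemplate:
    """A 73-bp selection template: defined flanks around a randomized core."""

    core: str
    left_flank: str = LEFT_FLANK
    right_flank: str = RIGHT_FLANK

    def __post_init__(self) -> None:
        total = len(self.left_flank) + len(self.core) + len(self.right_flank)
        if total != TEMPLATE_LENGTH:
            raise ValueError(f"template length {total} != {TEMPLATE_LENGTH}")
        if len(self.core) != CORE_LENGTH:
            raise ValueError(f"core length {len(self.core)} != {CORE_LENGTH}")

    @property
    def sequence(self) -> str:
        return self.left_flank + self.core + self.right_flank


@dataclasses.dataclass
class SelectionLibrary:
    """Weighted multiset of randomized cores at a given selection round."""

    cores: list[str]
    counts: np.ndarray
    round_index: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.cores) != len(self.counts):
            raise ValueError("cores and counts must have equal length")
        if len(self.cores) and (self.counts < 1).any():
            raise ValueError("counts must be >= 1")
        lengths = {len(c) for c in self.cores}
        if len(lengths) > 1:
            raise ValueError("all cores must have the same length")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_unique(self) -> int:
        return len(self.cores)

    def expand(self) -> list[str]:
        """The full multiset of cores, one entry per molecule."""
        return [c for c, k in zip(self.cores, self.counts) for _ in range(int(k))]


@dataclasses.dataclass
class AffinityModel:
    """Score-to-affinity map: K_D(seq) = kd_min * exp(beta * (s_max - s(seq))).

    ``s(seq)`` is the best log2-odds score of the motif over all placements on
    either strand of the core, so the maximal-score sequence binds at
    ``kd_min`` (nM) and every log-odds unit (bit) of score deficit multiplies
    K_D by ``exp(beta)``.  This single-site occupancy model stands in for the
    unknown true sequence-affinity map of the selected protein.
    """

    pwm: PWMotif
    kd_min: float
    beta: float
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.kd_min <= 0:
            raise ValueError("kd_min must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        self._lo = self.pwm.log_odds(pseudocount=self.pseudocount)
        self._smax = float(self._lo.max(axis=1).sum())

    @classmethod
    def from_iupac(cls, pattern: str, kd_min: float, beta: float, **kw) -> "AffinityModel":
        """Build the 'true' motif from an IUPAC consensus: probability uniform
        over each code's allowed bases, zero elsewhere."""
        rows = []
        for code in pattern.upper():
            mask = IUPAC_MASKS[code].astype(float)
            rows.append(mask / mask.sum())
        pwm = PWMotif(np.array(rows), name="planted")
        return cls(pwm=pwm, kd_min=kd_min, beta=beta, **kw)

    def scores(self, cores: Sequence[str] | np.ndarray) -> np.ndarray:
        """Best log2-odds score per core over all placements, both strands."""
        enc = cores if isinstance(cores, np.ndarray) else encode_many(cores)
        w = self._lo.shape[0]
        L = enc.shape[1]
        if L < w:
            raise ValueError(f"cores shorter ({L}) than motif width ({w})")
        lo_rc = self._lo[::-1, ::-1]
        n_off = L - w + 1
        best = np.full(enc.shape[0], -np.inf)
        for off in range(n_off):
            win = enc[:, off : off + w]
            fwd = self._lo[np.arange(w), win].sum(axis=1)
            rev = lo_rc[np.arange(w), win].sum(axis=1)
            np.maximum(best, np.maximum(fwd, rev), out=best)
        return best

    def kd(self, cores: Sequence[str] | np.ndarray) -> np.ndarray:
        """Per-core dissociation constant in nM."""
        s = self.scores(cores)
        return self.kd_min * np.exp(self.beta * (self._smax - s))


@dataclasses.dataclass
class RepsaConfig:
    """Per-experiment selection parameters.

    ``protein_conc`` (nM) and ``cleavage_efficiency`` may be scalars or
    per-round sequences; the enzyme schedule (FokI for early rounds, BpmI
    thereafter) is a label only — enzyme identity affects cleavage efficiency,
    not sequence specificity.
    """

    protein_conc: float | Sequence[float] = 34.0
    cleavage_efficiency: float | Sequence[float] = 0.9
    rounds: int = 5
    enzyme_schedule: tuple[str, ...] = ("FokI", "FokI", "BpmI", "BpmI", "BpmI")
    pcr_resampling_depth: int = 100_000
    seed: int = 0

    def _per_round(self, value, round_index: int) -> float:
        if np.isscalar(value):
            return float(value)
        return float(value[round_index])

    def conc(self, round_index: int) -> float:
        c = self._per_round(self.protein_conc, round_index)
        if c < 0:
            raise ValueError("protein concentration must be >= 0")
        return c

    def cleavage(self, round_index: int) -> float:
        e = self._per_round(self.cleavage_efficiency, round_index)
        if not 0 <= e <= 1:
            raise ValueError("cleavage_efficiency must be in [0, 1]")
        return e


def generate_library(
    n_templates: int, core_length: int = CORE_LENGTH, seed: int | None = None
) -> SelectionLibrary:
    """Draw ``n_templates`` i.i.d. uniform random cores (Round 0 library)."""
    if n_templates < 1 or core_length < 1:
        raise ValueError("n_templates and core_length must be >= 1")
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=(n_templates, core_length), dtype=np.int8)
    cores = decode_many(arr)
    uniq, counts = np.unique(cores, return_counts=True)
    return SelectionLibrary(cores=list(uniq), counts=counts, round_index=0)


def simulate_repsa_round(
    lib: SelectionLibrary,
    aff: AffinityModel,
    cfg: RepsaConfig,
    rng: np.random.Generator | None = None,
) -> SelectionLibrary:
    """One REPSA round: occupancy-dependent cleavage survival, then PCR resampling.

    Occupancy theta = C / (C + K_D(core)); survival probability
    theta + (1 - theta) * (1 - cleavage_efficiency).  Survivors are resampled
    multinomially with replacement to ``pcr_resampling_depth`` molecules.
    """
    if lib.n_unique == 0:
        raise ValueError("cannot select from an empty library")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, lib.round_index])
    conc = cfg.conc(lib.round_index)
    ce = cfg.cleavage(lib.round_index)
    kd = aff.kd(lib.cores)
    theta = conc / (conc + kd) if conc > 0 else np.zeros_like(kd)
    p_survive = theta + (1.0 - theta) * (1.0 - ce)
    survivors = rng.binomial(lib.counts, p_survive)
    total = survivors.sum()
    if total == 0:
        return SelectionLibrary([], np.empty(0, dtype=np.int64), lib.round_index + 1)
    new_counts = rng.multinomial(cfg.pcr_resampling_depth, survivors / total)
    keep = new_counts > 0
    return SelectionLibrary(
        cores=[c for c, k in zip(lib.cores, keep) if k],
        counts=new_counts[keep],
        round_index=lib.round_index + 1,
    )


def simulate_repsa(
    lib: SelectionLibrary, aff: AffinityModel, cfg: RepsaConfig
) -> list[SelectionLibrary]:
    """Run ``cfg.rounds`` selection rounds; returns the library after each round."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.rounds):
        lib = simulate_repsa_round(lib, aff, cfg, rng=rng)
        out.append(lib)
        if lib.n_unique == 0:
            break
    return out


def fraction_matching(
    lib: SelectionLibrary, pattern: str, max_mismatches: int = 0
) -> float:
    """Weighted fraction of library cores containing a consensus match.

    A core matches if any placement of the IUPAC ``pattern``, on either
    strand, has at most ``max_mismatches`` disallowed bases.
    """
    if lib.n_unique == 0:
        return 0.0
    enc = encode_many(lib.cores)
    hits = matches_pattern(enc, pattern, max_mismatches)
    return float(lib.counts[hits].sum() / lib.n_total)


def matches_pattern(enc: np.ndarray, pattern: str, max_mismatches: int = 0) -> np.ndarray:
    """Boolean per-row indicator of an IUPAC pattern match on either strand."""
    pattern = pattern.upper()
    w = len(pattern)
    L = enc.shape[1]
    if L < w:
        return np.zeros(enc.shape[0], dtype=bool)
    allowed = np.array([IUPAC_MASKS[c] for c in pattern])  # (w, 4)
    allowed_rc = np.array([IUPAC_MASKS[c] for c in revcomp(pattern)])
    hit = np.zeros(enc.shape[0], dtype=bool)
    for off in range(L - w + 1):
        win = enc[:, off : off + w]
        mm_f = (~allowed[np.arange(w), win]).sum(axis=1)
        mm_r = (~allowed_rc[np.arange(w), win]).sum(axis=1)
        hit |= (mm_f <= max_mismatches) | (mm_r <= max_mismatches)
    return hit


def reads_from_library(
    lib: SelectionLibrary,
    error_rate: float = 0.0,
    flank_corruption_rate: float = 0.0,
    seed: int | None = None,
    template: SelectionTemplate | None = None,
    phred: int = 30,
) -> list[SeqRecord]:
    """Sequencing reads: flank + core + flank with i.i.d. substitution errors.

    A ``flank_corruption_rate`` fraction of reads lose a random prefix of the
    left flank (truncation).  Every base carries the same Phred quality.
    """
    for name, rate in (("error_rate", error_rate), ("flank_corruption_rate", flank_corruption_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    left = LEFT_FLANK if template is None else template.left_flank
    right = RIGHT_FLANK if template is None else template.right_flank
    rng = np.random.default_rng(seed)
    cores = lib.expand()
    n = len(cores)
    left_enc = encode(left)
    right_enc = encode(right)
    full = np.concatenate(
        [
            np.tile(left_enc, (n, 1)),
            encode_many(cores),
            np.tile(right_enc, (n, 1)),
        ],
        axis=1,
    )
    if error_rate > 0:
        err = rng.random(full.shape) < error_rate
        shift = rng.integers(1, 4, size=full.shape, dtype=np.int8)
        full = np.where(err, (full + shift) % 4, full)
    corrupt = rng.random(n) < flank_corruption_rate
    trunc = np.where(corrupt, rng.integers(1, len(left) + 1, size=n), 0)
    records = []
    for i, row in enumerate(full):
        seq = "".join(DNA[b] for b in row[int(trunc[i]):])
        rec = SeqRecord(Seq(seq), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = [phred] * len(seq)
        records.append(rec)
    return records


def generate_genome(
    length: int,
    gc: float = 0.5,
    planted_sites: Sequence[tuple[str, int, str]] = (),
    seed: int | None = None,
    gene_length: tuple[int, int] = (600, 1200),
    intergenic: tuple[int, int] = (150, 400),
    name: str = "synthetic_chr",
) -> tuple[str, pd.DataFrame]:
    """A random genome with planted motif sites and a non-overlapping gene table.

    Background bases are i.i.d. with the stated GC fraction.  Each planted
    site ``(sequence, position, strand)`` is written at its 0-based forward
    position ('-' strand sites are written as the reverse complement).  The
    gene table tiles both strands with non-overlapping ORFs and always
    contains at least one divergent (head-to-head) pair; it is returned as a
    GFF3-style DataFrame with 1-based inclusive coordinates.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.int8)
    sites = sorted(planted_sites, key=lambda s: s[1])
    prev_end = -1
    for seq, pos, strand in sites:
        if pos < 0 or pos + len(seq) > length:
            raise ValueError(f"planted site at {pos} does not fit in genome of length {length}")
        if pos <= prev_end:
            raise ValueError(f"planted sites overlap at position {pos}")
        prev_end = pos + len(seq) - 1
        insert = seq if strand == "+" else revcomp(seq)
        arr[pos : pos + len(seq)] = encode(insert)
    genome = "".join(DNA[b] for b in arr)

    # Gene tiling: alternate strand blocks, force one divergent pair up front.
    rows = []
    pos = int(rng.integers(*intergenic))
    strands = ["-", "+"]  # genes 1 and 2 divergent (head-to-head)
    i = 0
    while True:
        glen = int(rng.integers(*gene_length))
        if pos + glen > length - 50:
            break
        strand = strands[i] if i < len(strands) else ("+" if rng.random() < 0.5 else "-")
        rows.append(
            {
                "seqid": name,
                "source": "selexscan",
                "type": "gene",
                "start": pos + 1,
                "end": pos + glen,
                "score": ".",
                "strand": strand,
                "frame": ".",
                "attributes": f"ID=gene{i + 1:04d}",
            }
        )
        pos += glen + int(rng.integers(*intergenic))
        i += 1
    features = pd.DataFrame(rows)
    return genome, features


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concs: Sequence[float],
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[Sensorgram]:
    """Closed-form 1:1 Langmuir sensorgrams at several analyte concentrations (nM).

    Association: R(t) = R_eq (1 - exp(-k_obs t)) with k_obs = kon C + koff and
    R_eq = rmax C / (C + koff/kon); dissociation decays from R(t_assoc) at
    rate koff.  Gaussian noise of ``noise_sd`` response units is added.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and rmax must all be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    out = []
    for conc in concs:
        resp = model_response(kon, koff, rmax, conc, times, t_switch=t_assoc)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
        out.append(Sensorgram(concentration=float(conc), times=times.copy(), responses=resp, t_switch=t_assoc))
    return out


def simulate_repa_bands(
    kd: float,
    concs: Sequence[float],
    cleavage_efficiency: float = 0.9,
    seed: int | None = None,
    noise_sd: float = 0.0,
    total_intensity: float = 1.0,
) -> list[RepaMeasurement]:
    """Cleavage-protection band intensities across a protein titration.

    The probe's uncleaved fraction is theta + (1 - theta)(1 - ce) with
    theta = C / (C + kd); the control lane has no binding site (kd = inf),
    so its uncleaved fraction is the enzyme-escape fraction (1 - ce) alone.
    """
    if not 0 <= cleavage_efficiency <= 1:
        raise ValueError("cleavage_efficiency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for conc in concs:
        theta = 0.0 if math.isinf(kd) else conc / (conc + kd)
        frac_probe = theta + (1 - theta) * (1 - cleavage_efficiency)
        frac_ctrl = 1 - cleavage_efficiency
        vals = np.array(
            [
                frac_probe * total_intensity,
                (1 - frac_probe) * total_intensity,
                frac_ctrl * total_intensity,
                (1 - frac_ctrl) * total_intensity,
            ]
        )
        if noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, noise_sd, size=4), 0.0, None)
        out.append(
            RepaMeasurement(
                concentration=float(conc),
                probe_uncleaved=float(vals[0]),
                probe_cleaved=float(vals[1]),
                control_uncleaved=float(vals[2]),
                control_cleaved=float(vals[3]),
            )
        )
    return out


def sample_site(pattern: str, rng: np.random.Generator) -> str:
    """One concrete realization of an IUPAC pattern (uniform within each code)."""
    out = []
    for code in pattern.upper():
        allowed = np.flatnonzero(IUPAC_MASKS[code])
        out.append(DNA[int(rng.choice(allowed))])
    return "".join(out)


def planted_core_library(
    n: int,
    pattern: str,
    prevalence: float,
    core_length: int = CORE_LENGTH,
    seed: int | None = None,
) -> list[str]:
    """Random cores, a ``prevalence`` fraction of which carry one sampled site.

    Each planted core embeds a fresh realization of the IUPAC ``pattern`` at a
    uniform random offset, on a uniform random strand.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if len(pattern) > core_length:
        raise ValueError("pattern longer than core")
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=(n, core_length), dtype=np.int8)
    planted = rng.random(n) < prevalence
    w = len(pattern)
    for i in np.flatnonzero(planted):
        site = sample_site(pattern, rng)
        if rng.random() < 0.5:
            site = revcomp(site)
        off = int(rng.integers(0, core_length - w + 1))
        arr[i, off : off + w] = encode(site)
    return decode_many(arr)
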