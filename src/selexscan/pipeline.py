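"""End-to-end orchestration: simulate -> refine -> discover -> extend -> scan -> annotate.

Each stage reads and writes on-disk artifacts (FASTQ/FASTA/MEME/GFF3/TSV/JSON)
so the corresponding CLI subcommands remain independently usable, and a JSON
manifest records the configuration, per-stage sub-seeds and SHA-256 hashes of
every output, making a run byte-reproducible under a fixed global seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .discovery import consensus_from_pwm, discover_motif, information_content
from .pwm import extend_palindromic, read_meme_minimal, write_meme_minimal
from .refine import deduplicate, refine_reads, write_cores_fasta
from .scan import annotate_hits, calls_to_frame, hits_to_frame, scan, write_gff3
from .simulate import (
    LEFT_FLANK,
    RIGHT_FLANK,
    AffinityModel,
    RepsaConfig,
    SelectionLibrary,
    generate_genome,
    generate_library,
    planted_core_library,
    reads_from_library,
    simulate_repsa,
)

logger = logging.getLogger("selexscan")

REQUIRED_BLOCKS = ("library", "affinity", "selection", "reads", "discover", "genome", "scan")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "library": {"n_templates": 5000, "core_length": 24, "planted_prevalence": 0.5},
    "affinity": {"consensus": "AWTGTRANNNNNNTYACAWT", "kd_min": 3.0, "beta": 1.0},
    "selection": {
        "rounds": 5,
        "protein_conc": 34.0,
        "cleavage_efficiency": 0.9,
        "pcr_resampling_depth": 5000,
    },
    "reads": {"error_rate": 0.005, "flank_corruption_rate": 0.02, "phred": 30},
    "refine": {"min_mean_quality": 20.0, "core_length": 24},
    "discover": {"width": 20, "palindromic": True, "n_starts": 8, "sample": 1000},
    "extend": {"block_start": 1, "block_end": 10},
    "genome": {"length": 50_000, "gc": 0.69, "n_planted": 5},
    "scan": {"p_threshold": 1e-4},
    "annotate": {"window_upstream": 200, "window_downstream": 20, "far_threshold": 5e-6},
}


class PipelineConfigError(ValueError):
    """Configuration failed schema validation; names the offending block."""


def default_config() -> dict:
    """A small demo configuration (deep copy) that runs in well under a minute."""
    return json.loads(json.dumps(DEFAULT_CONFIG))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise PipelineConfigError("configuration must be a mapping")
    for block in REQUIRED_BLOCKS:
        if block not in cfg:
            raise PipelineConfigError(f"missing required configuration block: {block!r}")
    if "seed" not in cfg:
        raise PipelineConfigError("missing required configuration block: 'seed'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # One recorded sub-seed per stochastic stage, derived from the global seed.
    ss = np.random.SeedSequence(int(config["seed"]))
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("library", "selection", "reads", "discover", "genome"), ss.spawn(5)
        )
    }
    manifest: dict = {
        "version": __version__,
        "config": config,
        "stage_seeds": stage_seeds,
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], **info) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
                **info,
            }
        )
        logger.info("stage %s complete: %s", stage, [str(p) for p in outputs])

    try:
        # -- simulate ------------------------------------------------------
        lib_cfg, aff_cfg, sel_cfg = config["library"], config["affinity"], config["selection"]
        prevalence = lib_cfg.get("planted_prevalence", 0.0)
        if prevalence > 0:
            # Start from a pool already carrying consensus sites: at demo scale
            # a purely random library holds no perfect dyad site to enrich.
            cores = planted_core_library(
                lib_cfg["n_templates"],
                config["affinity"]["consensus"],
                prevalence,
                core_length=lib_cfg.get("core_length", 24),
                seed=stage_seeds["library"],
            )
            uniq, counts = np.unique(cores, return_counts=True)
            lib = SelectionLibrary(cores=list(uniq), counts=counts, round_index=0)
        else:
            lib = generate_library(
                lib_cfg["n_templates"], lib_cfg.get("core_length", 24),
                seed=stage_seeds["library"],
            )
        aff = AffinityModel.from_iupac(
            aff_cfg["consensus"], kd_min=aff_cfg["kd_min"], beta=aff_cfg["beta"]
        )
        repsa = RepsaConfig(
            protein_conc=sel_cfg["protein_conc"],
            cleavage_efficiency=sel_cfg["cleavage_efficiency"],
            rounds=sel_cfg["rounds"],
            pcr_resampling_depth=sel_cfg["pcr_resampling_depth"],
            seed=stage_seeds["selection"],
        )
        rounds = simulate_repsa(lib, aff, repsa)
        final = rounds[-1]
        reads = reads_from_library(
            final,
            error_rate=config["reads"].get("error_rate", 0.0),
            flank_corruption_rate=config["reads"].get("flank_corruption_rate", 0.0),
            phred=config["reads"].get("phred", 30),
            seed=stage_seeds["reads"],
        )
        fastq = outdir / "selected_reads.fastq"
        from Bio import SeqIO

        SeqIO.write(reads, str(fastq), "fastq")
        record("simulate", [fastq], n_reads=len(reads), rounds=len(rounds))

        # -- refine ----------------------------------------------------------
        ref_cfg = config.get("refine", {})
        refined = refine_reads(
            str(fastq),
            left_anchor=LEFT_FLANK,
            right_anchor=RIGHT_FLANK,
            core_length=ref_cfg.get("core_length", 24),
            min_mean_quality=ref_cfg.get("min_mean_quality", 20.0),
        )
        refined = deduplicate(refined)
        cores_fa = outdir / "cores.fasta"
        stats_json = outdir / "refine_stats.json"
        write_cores_fasta(refined.cores, cores_fa)
        stats_json.write_text(json.dumps(refined.stats, indent=2) + "\n")
        record("refine", [cores_fa, stats_json], **refined.stats)

        # -- discover --------------------------------------------------------
        dis_cfg = config["discover"]
        pwm = discover_motif(
            refined.cores,
            width=dis_cfg.get("width", 20),
            palindromic=dis_cfg.get("palindromic", True),
            n_starts=dis_cfg.get("n_starts", 8),
            sample=dis_cfg.get("sample"),
            seed=stage_seeds["discover"],
        )
        consensus = consensus_from_pwm(pwm)
        motif_file = outdir / "motif.meme"
        report_file = outdir / "motif_report.json"
        write_meme_minimal(pwm, motif_file)
        report_file.write_text(
            json.dumps(
                {
                    "consensus": consensus.iupac,
                    "half_site_length": consensus.half_site_length,
                    "spacer_length": consensus.spacer_length,
                    "information_content_bits": float(information_content(pwm).sum()),
                    "nsites": pwm.nsites,
                    "log_likelihood_ratio": pwm.score_significance,
                },
                indent=2,
            )
            + "\n"
        )
        record("discover", [motif_file, report_file], consensus=consensus.iupac)

        # -- extend ----------------------------------------------------------
        ext_cfg = config.get("extend", {})
        extended = extend_palindromic(
            read_meme_minimal(motif_file),
            ext_cfg.get("block_start", 1),
            ext_cfg.get("block_end", pwm.width // 2),
        )
        ext_file = outdir / "motif_extended.meme"
        write_meme_minimal(extended, ext_file)
        record("extend", [ext_file], width=extended.width)

        # -- genome ----------------------------------------------------------
        gen_cfg = config["genome"]
        rng = np.random.default_rng(stage_seeds["genome"])
        n_plant = gen_cfg.get("n_planted", 5)
        length = gen_cfg["length"]
        site_len = extended.width
        positions = np.sort(
            rng.choice(length // (2 * site_len) - 2, size=n_plant, replace=False)
        ) * (2 * site_len)
        planted = [
            (extended.max_score_word(), int(pos), "+" if rng.random() < 0.5 else "-")
            for pos in positions
        ]
        genome_seq, features = generate_genome(
            length, gc=gen_cfg.get("gc", 0.5), planted_sites=planted, seed=stage_seeds["genome"]
        )
        genome_fa = outdir / "genome.fasta"
        gff = outdir / "features.gff3"
        genome_fa.write_text(f">synthetic_chr\n{genome_seq}\n")
        write_gff3(features, gff)
        record("genome", [genome_fa, gff], n_planted=n_plant, n_genes=len(features))

        # -- scan ------------------------------------------------------------
        hits = scan(
            str(genome_fa),
            read_meme_minimal(ext_file),
            p_threshold=config["scan"].get("p_threshold", 1e-4),
        )
        hits_tsv = outdir / "hits.tsv"
        hits_to_frame(hits, motif_id=extended.name).to_csv(hits_tsv, sep="\t", index=False)
        record("scan", [hits_tsv], n_hits=len(hits))

        # -- annotate --------------------------------------------------------
        ann_cfg = config.get("annotate", {})
        calls = annotate_hits(
            hits,
            gff,
            window_upstream=ann_cfg.get("window_upstream", 200),
            window_downstream=ann_cfg.get("window_downstream", 20),
            far_threshold=ann_cfg.get("far_threshold", 5e-6),
        )
        calls_tsv = outdir / "promoter_calls.tsv"
        calls_to_frame(calls).to_csv(calls_tsv, sep="\t", index=False)
        record("annotate", [calls_tsv], n_calls=len(calls))
    except PipelineConfigError:
        raise
    except Exception as exc:
        stage = manifest["stages"][-1]["name"] if manifest["stages"] else "simulate"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
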