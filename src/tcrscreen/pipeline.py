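"""End-to-end orchestration: simulate -> process -> deconvolve -> train ->
mine -> benchmark -> cross-reactivity scan, from one configuration.

Every stage writes its outputs under the run directory and contributes a
summary block to a JSON manifest (seeds, input hashes, per-stage statistics),
so a run is fully described by its config and reproducible from its seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import baselines, datasets
from .alphabet import AMINO_ACIDS
from .classifier import ClassifierConfig, crossvalidate, train_classifier
from .crossreactivity import ScanConfig, scan_proteome
from .deconvolution import deconvolve_cores, estimate_background
from .mining import filter_repertoire, rank_repertoire, select_candidates
from .processing import FilterAudit, extract_cores, filter_clonotypes, read_clonotype_table
from .synthetic import (
    LibraryDesign,
    PlantedMotif,
    RepertoireSimConfig,
    ScreenSimConfig,
    simulate_panning,
    sample_input_library,
    generate_repertoire,
    write_airr_tsv,
    write_mixcr_tsv,
    write_truth_tsv,
)

logger = logging.getLogger(__name__)

TEMPLATE_CORE = "YVGNT"


def default_planted_motif(
    lengths: tuple[int, ...] = (5,), beta: float = 1.0, seed: int = 0
) -> PlantedMotif:
    """A screen-like planted motif mirroring the recovered binding motifs:
    Asn/Tyr/Ser-enriched position 1, aliphatic (Leu/Ile/Val) position 2,
    Gly position 3, and lower specificity toward the C-terminal end.
    """
    rng = np.random.default_rng(seed)
    pwms: dict[int, np.ndarray] = {}
    for length in lengths:
        pwm = rng.dirichlet(np.ones(20) * 2.0, size=length)
        for p, (enriched, mass) in enumerate(
            [("NYS", 0.8), ("LIV", 0.9), ("G", 0.9)]
        ):
            if p < length:
                row = np.full(20, (1.0 - mass) / 20)
                for aa in enriched:
                    row[AMINO_ACIDS.index(aa)] = mass / len(enriched)
                pwm[p] = row / row.sum()
        pwm /= pwm.sum(axis=1, keepdims=True)
        pwms[length] = pwm
    return PlantedMotif(pwms=pwms, beta=beta)


@dataclass
class RunConfig:
    """Stage-wise configuration of a full synthetic run."""

    outdir: str = "tcrscreen_run"
    seed: int = 0
    log_level: str = "INFO"
    design: LibraryDesign = field(default_factory=LibraryDesign)
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    repertoire: RepertoireSimConfig = field(default_factory=RepertoireSimConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    motif_lengths: tuple[int, ...] = (5,)
    motif_beta: float = 1.0
    n_spike: int = 5
    n_candidates: int = 30
    run_cv: bool = False
    cv_folds: int = 5
    proteome_fasta: str | None = None
    synthetic_proteome_proteins: int = 30
    synthetic_proteome_length: int = 300

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("design", LibraryDesign),
            ("screen", ScreenSimConfig),
            ("repertoire", RepertoireSimConfig),
            ("classifier", ClassifierConfig),
            ("scan", ScanConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                for tup_key in ("core_lengths", "spike_in", "spike_positions"):
                    if tup_key in block and isinstance(block[tup_key], list):
                        block[tup_key] = tuple(block[tup_key])
                kwargs[key] = sub(**block)
        if "motif_lengths" in kwargs:
            kwargs["motif_lengths"] = tuple(kwargs["motif_lengths"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_synthetic_proteome(path: Path, cfg: RunConfig) -> None:
    """A labeled synthetic proteome with epitope-like peptides implanted."""
    rng = np.random.default_rng(cfg.seed + 7)
    aa = np.array(list(AMINO_ACIDS))
    implants = ["FLTLWLTQV", "GLRMWIKQV", "TQIQWATQV"]
    with open(path, "w") as fh:
        for i in range(cfg.synthetic_proteome_proteins):
            seq = "".join(rng.choice(aa, size=cfg.synthetic_proteome_length))
            if i < len(implants):
                pos = int(rng.integers(0, len(seq) - 9))
                seq = seq[:pos] + implants[i] + seq[pos + 9 :]
            fh.write(f">SYNTH{i:04d} synthetic protein\n{seq}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }
    design = config.design

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    try:
        # -- simulate -----------------------------------------------------
        screen_cfg = ScreenSimConfig(**{**asdict(config.screen), "seed": config.seed})
        motif = default_planted_motif(
            config.motif_lengths, beta=config.motif_beta, seed=config.seed
        )
        input_table = sample_input_library(design, screen_cfg)
        screen = simulate_panning(input_table, motif, screen_cfg, design)
        planted_binders = (
            screen.output_table.loc[screen.truth.eq("binder").to_numpy(), "cdr3_aa"]
            .unique()
            .tolist()
        )
        spikes = tuple(planted_binders[: config.n_spike])
        rep_cfg = RepertoireSimConfig(
            **{
                **asdict(config.repertoire),
                "seed": config.seed,
                "spike_in": spikes,
                "spike_positions": None,
            }
        )
        repertoire = generate_repertoire(rep_cfg, design)
        write_mixcr_tsv(input_table, outdir / "input_library.tsv")
        write_mixcr_tsv(screen.output_table, outdir / "output_library.tsv")
        write_airr_tsv(repertoire, outdir / "repertoire.tsv")
        write_truth_tsv(screen, outdir / "truth.tsv")
        for name in ("input_library", "output_library", "repertoire", "truth"):
            record(name, outdir / f"{name}.tsv")
        manifest["stages"]["simulate"] = {
            "n_input_clonotypes": len(input_table),
            "n_output_rows": len(screen.output_table),
            "n_repertoire": len(repertoire),
            "n_spiked": len(spikes),
        }

        # -- process ------------------------------------------------------
        inp = read_clonotype_table(outdir / "input_library.tsv", "mixcr")
        out = read_clonotype_table(outdir / "output_library.tsv", "mixcr")
        audit = FilterAudit()
        out_filtered = filter_clonotypes(out, TEMPLATE_CORE, design, audit)
        audit.to_json(outdir / "filter_audit.json")
        record("filter_audit", outdir / "filter_audit.json")
        input_cores = extract_cores(inp, design)
        output_cores = extract_cores(out_filtered, design)
        output_cores.to_frame().to_csv(outdir / "output_cores.tsv", sep="\t", index=False)
        record("output_cores", outdir / "output_cores.tsv")
        manifest["stages"]["process"] = {
            "filters": audit.__dict__,
            "core_lengths": {
                str(k): len(v) for k, v in output_cores.cores.items()
            },
        }

        # -- deconvolve ---------------------------------------------------
        background = estimate_background(input_cores)
        deconv = deconvolve_cores(output_cores, background, seed=config.seed)
        binder_seqs = sorted(
            design.embed(core)
            for res in deconv.values()
            for core in res.binders
        )
        summary = {
            str(length): {
                "n_binders": len(res.binders),
                "n_contaminants": len(res.contaminants),
                "max_ic_bits": float(res.information_content.max()),
                "ic_pass": res.ic_pass,
                "flat_weight": float(res.model.weights[-1]),
            }
            for length, res in deconv.items()
        }
        with open(outdir / "deconvolution.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        record("deconvolution", outdir / "deconvolution.json")
        manifest["stages"]["deconvolve"] = summary

        # -- train --------------------------------------------------------
        output_seqs = set(out["cdr3_aa"])
        negatives = sorted(set(inp["cdr3_aa"]) - output_seqs)
        clf_cfg = ClassifierConfig(
            **{**asdict(config.classifier), "seed": config.seed}
        )
        model = train_classifier(binder_seqs, negatives, clf_cfg)
        model.save(outdir / "model.npz")
        manifest["stages"]["train"] = {
            "n_positives": len(binder_seqs),
            "n_negatives_pool": len(negatives),
            "epochs_run": len(model.history["train_loss"]),
            "weights_sha256": model.weights_digest(),
        }
        if config.run_cv:
            report = crossvalidate(binder_seqs, negatives, clf_cfg, config.cv_folds)
            report.to_json(outdir / "cv_report.json")
            record("cv_report", outdir / "cv_report.json")
            manifest["stages"]["cv"] = {
                "mean_auc": report.mean_auc,
                "fold_aucs": report.fold_aucs,
            }

        # -- mine ---------------------------------------------------------
        rep = filter_repertoire(repertoire, design)
        scored = rank_repertoire(model, rep, design)
        candidates = select_candidates(
            scored, min(config.n_candidates, len(scored.table)), "broad_range",
            seed=config.seed,
        )
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        scored.score_histogram().to_csv(
            outdir / "score_distribution.tsv", sep="\t", index=False
        )
        record("candidates", outdir / "candidates.tsv")
        record("score_distribution", outdir / "score_distribution.tsv")
        spiked_ranks = (
            scored.table.loc[scored.table.get("spiked", False).astype(bool), "rank"]
            .tolist()
            if "spiked" in scored.table.columns
            else []
        )
        manifest["stages"]["mine"] = {
            "filters": rep.attrs.get("filter_tallies", {}),
            "n_candidates": len(candidates),
            "spiked_ranks": spiked_ranks,
        }

        # -- benchmark ----------------------------------------------------
        labeled = datasets.benchmark_labeled_set()
        methods = {
            "published_model_scores": labeled["score"].to_numpy(),
            "exact_match": baselines.exact_match_scorer(output_seqs),
            "blosum_similarity": baselines.blosum_similarity_scorer(
                datasets.REFERENCE_CDR3B
            ),
            "cdr3_distance": baselines.cdr3_distance_scorer(datasets.REFERENCE_CDR3B),
        }
        bench = baselines.benchmark_methods(labeled, methods)
        bench.to_csv(outdir / "benchmark.tsv", sep="\t", index=False)
        record("benchmark", outdir / "benchmark.tsv")
        manifest["stages"]["benchmark"] = dict(
            zip(bench["method"], bench["auc"].round(6))
        )

        # -- cross-reactivity scan ----------------------------------------
        proteome = config.proteome_fasta
        if proteome is None:
            proteome = outdir / "synthetic_proteome.fasta"
            _write_synthetic_proteome(Path(proteome), config)
            record("synthetic_proteome", Path(proteome))
        report = scan_proteome(proteome, config.scan, top_n=25)
        report.to_csv(outdir / "crossreactivity.tsv", sep="\t", index=False)
        record("crossreactivity", outdir / "crossreactivity.tsv")
        manifest["stages"]["xreact"] = {
            "n_reported": len(report),
            "top_peptides": report["peptide"].head(3).tolist(),
        }
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "simulate"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
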