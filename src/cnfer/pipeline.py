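"""End-to-end orchestration: config, pipeline stages, reports, training.

The pipeline runs: count -> correct -> center -> segment(reference) ->
project -> rank -> weights -> similarity -> significance -> combined call,
and writes a JSON summary plus TSV artifacts. Outputs are deterministic for
a fixed config, inputs and seed; the config hash is recorded in every
report for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bin_grid import BinGrid, GridError, annotate_bins, build_bin_grid, \
    read_chrom_sizes
from .coverage import CoverageProfile, center_to_deviation, correct_bias, \
    count_reads, profile_from_counts
from .segmentation import project_segments, rank_segments, \
    segment_reference
from .significance import CtDNACall, call_ctdna, classify_query, \
    extract_features, dunn_pvalue_matrix, kendall_segments, load_classifier, \
    section_features, train_classifier
from .similarity import SimilarityConfig, bin_weights, calibrate_lambda, \
    compute_weights, estimate_tf, solve_similarity
from .simulate import AdmixtureSpec, TruthProfile, make_synthetic_grid, \
    make_truth_profile, null_deviation_sampler, simulate_bin_counts

logger = logging.getLogger("cnfer")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; mirrors the CLI flags."""

    reference: str = ""           # BAM or profile TSV
    query: str = ""               # BAM or profile TSV
    reference_tf: float = 0.0     # required, from any external purity tool
    grid: str = ""                # annotated grid TSV (or build from tracks)
    mappability: str = ""
    chrom_sizes: str = ""
    gc_fasta: str = ""
    reptiming: str = ""
    model: str = ""               # trained classifier (joblib)
    out_dir: str = "cnfer_out"
    bin_width: int = 100_000
    step: int = 10_000
    mappability_cutoff: float = 0.2
    mapq_min: int = 30
    fragment_max: int | None = None
    penalty_scale: float = 5.0
    min_seg_bins: int = 5
    lambda_penalty: float | None = None   # None -> calibrated against nulls
    llod_threshold: float = 0.002
    dispersion: float = 0.1               # null model for lambda calibration
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.reference_tf <= 1:
            raise ValueError("reference_tf is required and must be in (0, 1]")
        if not (0 <= self.mappability_cutoff <= 1):
            raise ValueError("mappability_cutoff must be in [0, 1]")
        if self.llod_threshold < 0 or self.min_seg_bins < 1:
            raise ValueError("thresholds out of range")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key = value`` text config."""
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key: {key}")
            if value.lower() in {"none", ""}:
                kwargs[key] = None
            else:
                anno = str(types[key])
                if "int" in anno and "float" not in anno:
                    kwargs[key] = int(value)
                elif "float" in anno:
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def resolve_grid(config: RunConfig) -> BinGrid:
    if config.grid:
        return BinGrid.from_tsv(config.grid, bin_width=config.bin_width)
    if not (config.mappability and config.chrom_sizes):
        raise GridError("either a grid TSV or mappability + chrom_sizes "
                        "tracks are required")
    grid = build_bin_grid(
        config.mappability, read_chrom_sizes(config.chrom_sizes),
        bin_width=config.bin_width, step=config.step,
        mappability_cutoff=config.mappability_cutoff)
    return annotate_bins(grid, gc_source=config.gc_fasta or None,
                         reptiming_track=config.reptiming or None)


def resolve_profile(path: str, grid: BinGrid, config: RunConfig,
                    sample_id: str) -> CoverageProfile:
    """Load a profile from a BAM (counted fresh) or a precomputed TSV."""
    p = Path(path)
    if p.suffix.lower() == ".bam":
        prof = count_reads(p, grid, mapq_min=config.mapq_min,
                           fragment_max=config.fragment_max,
                           sample_id=sample_id)
        return center_to_deviation(correct_bias(prof, grid))
    prof = CoverageProfile.from_tsv(p, sample_id=sample_id)
    if prof.deviation is None:
        if prof.log2_ratio is None:
            prof = correct_bias(prof, grid)
        prof = center_to_deviation(prof)
    return prof


def run_pipeline(config: RunConfig, grid: BinGrid | None = None,
                 reference: CoverageProfile | None = None,
                 query: CoverageProfile | None = None) -> dict:
    """Execute the full tumor-informed analysis for one query sample.

    Inputs may be passed in memory (grid/reference/query) or resolved from
    the config paths. Returns a results dict; artifacts are written by
    :func:`write_report`.
    """
    config.validate()
    stage = "grid"
    try:
        if grid is None:
            grid = resolve_grid(config)
        stage = "coverage"
        if reference is None:
            reference = resolve_profile(config.reference, grid, config,
                                        "reference")
        if query is None:
            query = resolve_profile(config.query, grid, config, "query")

        stage = "segmentation"
        segs = segment_reference(reference, grid,
                                 penalty_scale=config.penalty_scale,
                                 min_seg_bins=config.min_seg_bins)
        segs = rank_segments(project_segments(segs, query))

        stage = "similarity"
        sim_cfg = SimilarityConfig(lambda_penalty=config.lambda_penalty)
        weights = compute_weights(segs, config.reference_tf, sim_cfg)
        w_bins = bin_weights(segs, weights)
        segs.segments["weight"] = weights.weights

        lam = config.lambda_penalty
        if lam is None:
            depth = float(np.mean(query.raw_counts)) if \
                query.raw_counts.any() else 1000.0
            sampler = null_deviation_sampler(grid, depth, config.dispersion)
            lam = calibrate_lambda(reference.deviation, w_bins, sampler,
                                   seed=config.seed)
        result = solve_similarity(reference.deviation, query.deviation,
                                  w_bins, lam,
                                  reference_id=reference.sample_id,
                                  query_id=query.sample_id)
        result = estimate_tf(result, config.reference_tf)

        stage = "significance"
        tau, tau_p = kendall_segments(segs)
        matrix = dunn_pvalue_matrix(query, segs)
        features = section_features(matrix, segs, tau=tau, tau_p=tau_p)

        svm_pred = None
        decision = None
        if config.model:
            bundle = load_classifier(config.model)
            svm_pred, decision = classify_query(features, bundle)

        stage = "call"
        if svm_pred is None:
            call = CtDNACall(
                tf_estimate=result.tf_estimate, svm_prediction=False,
                positive=bool(result.tf_estimate >= config.llod_threshold),
                llod_threshold=config.llod_threshold)
            call_basis = "tf_only (no classifier supplied)"
        else:
            call = call_ctdna(result.tf_estimate, svm_pred,
                              threshold=config.llod_threshold)
            call_basis = "tf_and_svm"
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {
        "grid": grid,
        "reference": reference,
        "query": query,
        "segments": segs,
        "weights": weights,
        "similarity": result,
        "features": features,
        "pvalue_matrix": matrix,
        "svm_prediction": svm_pred,
        "svm_decision": decision,
        "call": call,
        "call_basis": call_basis,
        "lambda": lam,
        "config": config,
    }


def write_report(results: dict, out_dir: str | Path | None = None) -> Path:
    """Write the JSON summary and TSV artifacts of a completed run."""
    config: RunConfig = results["config"]
    out = Path(out_dir or config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    grid: BinGrid = results["grid"]
    results["reference"].to_tsv(out / "reference_profile.tsv", grid)
    results["query"].to_tsv(out / "query_profile.tsv", grid)
    results["segments"].to_tsv(out / "segments.tsv")
    results["pvalue_matrix"].to_frame().to_csv(
        out / "pvalue_matrix.tsv", sep="\t", index=False,
        float_format="%.6g")

    sim = results["similarity"]
    report = {
        "cnfer_version": __version__,
        "config_hash": config.config_hash(),
        "reference_id": sim.reference_id,
        "query_id": sim.query_id,
        "similarity_score": sim.score,
        "tf_reference": sim.tf_reference,
        "tf_estimate": sim.tf_estimate,
        "lambda": results["lambda"],
        "k": sim.k,
        "n_segments": results["segments"].n_segments,
        "features": results["features"].to_dict(),
        "svm_prediction": results["svm_prediction"],
        "svm_decision": results["svm_decision"],
        "call": results["call"].to_dict(),
        "call_basis": results["call_basis"],
        "seed": config.seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True) + "\n")
    return out / "report.json"


# ---------------------------------------------------------------------------
# Default classifier training on simulator-generated dilutions


DEFAULT_TRAIN_TFS = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1)


def train_default_classifier(
    grid: BinGrid | None = None,
    truth: TruthProfile | None = None,
    seed: int = 0,
    tf_positives: tuple[float, ...] = DEFAULT_TRAIN_TFS,
    n_replicates: int = 100,
    depth_equivalent: float = 1.0,
    dispersion: float = 0.1,
    reference_tf: float = 0.6,
    gi_level: float = 0.4,
) -> dict:
    """Train the significance classifier on a simulated dilution corpus.

    Positives span the TF ladder, negatives are tumor-free admixtures of the
    same genome, all at the stated depth equivalent. The reference is a
    high-TF admixture of the same truth profile, segmented once; every
    training sample is projected onto that segmentation and featurized.
    """
    ss = np.random.SeedSequence(seed)
    if grid is None:
        grid = make_synthetic_grid(seed=seed)
    if truth is None:
        truth = make_truth_profile(grid, gi_level=gi_level, seed=seed)

    children = iter(ss.spawn(2 + (len(tf_positives) + 1) * n_replicates))
    ref_spec = AdmixtureSpec(tumor_fraction=reference_tf,
                             depth_equivalent=depth_equivalent,
                             dispersion=dispersion)
    ref_raw = simulate_bin_counts(truth, ref_spec, grid,
                                  rng=np.random.default_rng(next(children)))
    reference = profile_from_counts(ref_raw.raw_counts, grid,
                                    sample_id="train_reference")
    segs = segment_reference(reference, grid)

    X, y = [], []
    conditions = [(tf, 1) for tf in tf_positives] + [(0.0, 0)]
    for tf, label in conditions:
        for _ in range(n_replicates):
            spec = AdmixtureSpec(tumor_fraction=tf,
                                 depth_equivalent=depth_equivalent,
                                 dispersion=dispersion)
            raw = simulate_bin_counts(
                truth, spec, grid, rng=np.random.default_rng(next(children)))
            prof = profile_from_counts(raw.raw_counts, grid, sample_id="train")
            proj = rank_segments(project_segments(segs, prof))
            feats = extract_features(prof, proj)
            X.append(feats.to_vector())
            y.append(label)

    bundle = train_classifier(np.asarray(X), np.asarray(y), seed=seed)
    bundle["training"] = {
        "tf_positives": list(tf_positives),
        "n_replicates": n_replicates,
        "depth_equivalent": depth_equivalent,
        "dispersion": dispersion,
        "reference_tf": reference_tf,
        "gi_level": gi_level,
        "seed": seed,
    }
    return bundle
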