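"""End-to-end pipeline: filters -> diversity/selfing -> AMOVA -> linkage ->
PCA/admixture -> introduction inference -> range expansion.

Every stage writes machine-readable TSV/JSON into the output directory and
the run is summarized in ``manifest.json`` (package version, seeds,
thresholds, input checksums). Reruns with the same config and inputs produce
byte-identical outputs (floats are written at fixed precision and no
timestamps are recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import amova
from .clustering import estimate_admixture, pca_genotypes, select_k
from .expansion import accumulation_curve, bin_records, breakpoint_comparison, \
    lag_phase_regression
from .introductions import iterative_peeling
from .io import apply_matrix_filters, read_genotypes, read_metadata, \
    read_occurrences, write_genotypes
from .linkage import rbar_d
from .popgen import diversity_summary

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genotypes: str = ""
    metadata: str = ""
    occurrences: str | None = None
    genotype_format: str = "auto"
    output_dir: str = "invadepop_out"
    max_missing_fraction: float = 0.75
    min_presence_fraction: float = 0.10
    rare_maf_threshold: float = 0.10
    k_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    n_permutations: int = 199
    seed: int = 0
    cluster_source: str = "admixture"  # or "metadata_site"
    peeling_removal: str = "private"
    grid_spacing: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        for name, lo, hi in (("max_missing_fraction", 0, 1),
                             ("min_presence_fraction", 0, 1),
                             ("rare_maf_threshold", 0, 0.5)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.seed is None:
            raise ValueError("a seed is mandatory (stochastic stages)")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(payload), indent=2,
                               sort_keys=True, default=_json_default) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as files)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "setup"
    try:
        stage = "read"
        g = read_genotypes(config.genotypes, format=config.genotype_format)
        metadata = read_metadata(config.metadata)

        stage = "filter"
        g = apply_matrix_filters(g, config.max_missing_fraction,
                                 config.min_presence_fraction)
        missing_meta = [s for s in g.samples
                        if s not in set(metadata["sample"])]
        if missing_meta:
            raise ValueError(f"genotyped samples without metadata: "
                             f"{missing_meta[:5]}")
        metadata = metadata[metadata["sample"].isin(g.samples)]
        write_genotypes(g, out / "filtered_genotypes.tsv")
        summary["filtered"] = {"n_samples": g.n_samples, "n_loci": g.n_loci}

        meta_idx = metadata.set_index("sample").loc[g.samples]
        localities = meta_idx["site"].to_numpy(object)
        regions = meta_idx["ecoregion"].to_numpy(object)

        stage = "clustering"
        pca = pca_genotypes(g, n_components=min(10, g.n_samples - 1, g.n_loci))
        pd.DataFrame(pca.scores, index=g.samples,
                     columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
                     ).to_csv(out / "pca_scores.tsv", sep="\t",
                              float_format="%.6g")
        sel = select_k(g, config.k_range, seeds=(config.seed, config.seed + 1),
                       holdout_fraction=0.05)
        model = estimate_admixture(g, sel.chosen, seed=config.seed)
        qdf = pd.DataFrame(model.Q, index=g.samples,
                           columns=[f"cluster{k+1}" for k in range(sel.chosen)])
        qdf.to_csv(out / "admixture_Q.tsv", sep="\t", float_format="%.6g")
        _write_json({"ks": sel.ks, "cv_errors": sel.cv_errors,
                     "chosen_k": sel.chosen}, out / "k_selection.json")
        summary["clustering"] = {
            "chosen_k": sel.chosen,
            "pc_variance": pca.explained_variance_ratio[:3].tolist(),
        }
        if config.cluster_source == "admixture":
            clusters = np.array([f"cluster{k+1}" for k in model.hard_labels()],
                                dtype=object)
        else:
            clusters = localities

        stage = "diversity"
        table = diversity_summary(g, clusters)
        table.to_csv(out / "diversity.tsv", sep="\t", float_format="%.6g")
        summary["diversity"] = table.to_dict("index")

        stage = "amova"
        am = amova(g, localities, regions,
                   n_permutations=config.n_permutations, seed=config.seed)
        am.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False,
                             float_format="%.6g")
        summary["amova"] = {"phi": am.phi, "percent": am.percent,
                            "p_values": am.p_values}

        stage = "linkage"
        ia = rbar_d(g, n_permutations=config.n_permutations, seed=config.seed)
        _write_json(dataclasses.asdict(ia), out / "index_of_association.json")
        summary["linkage"] = {"rbar_d": ia.rbar_d, "p": ia.p_value}

        stage = "introductions"
        inference = iterative_peeling(
            g, metadata, clusters, rare_threshold=config.rare_maf_threshold,
            removal=config.peeling_removal,
        )
        intro_payload = []
        for rnd in inference.rounds:
            rnd.density.to_csv(out / f"rare_density_round{rnd.round_index}.tsv",
                               sep="\t", index=False, float_format="%.6g")
            intro_payload.append({
                "round": rnd.round_index,
                "focal_cluster": rnd.focal_cluster,
                "peak_site": rnd.peak_site,
                "peak_lat": rnd.peak_lat, "peak_lon": rnd.peak_lon,
                "n_rare": rnd.n_rare,
                "n_removed_loci": len(rnd.removed_loci),
                "decay_spearman_rho": (rnd.decay.spearman_rho
                                       if rnd.decay else None),
            })
        _write_json({"rounds": intro_payload,
                     "stop_reason": inference.stop_reason},
                    out / "introductions.json")
        summary["introductions"] = intro_payload

        if config.occurrences:
            stage = "expansion"
            records = read_occurrences(config.occurrences)
            grid = bin_records(records)
            curve = accumulation_curve(grid)
            curve.to_csv(out / "accumulation_curve.tsv", sep="\t", index=False)
            fit = lag_phase_regression(curve)
            cmp_fit = breakpoint_comparison(curve)
            _write_json({"fit": dataclasses.asdict(fit),
                         "breakpoint": cmp_fit}, out / "lag_phase.json")
            summary["expansion"] = {"slope": fit.slope, "r2": fit.r_squared,
                                    "delta_aic": cmp_fit["delta_aic"]}
        else:
            logger.info("no occurrence records supplied; "
                        "range-expansion stage skipped")
            summary["expansion"] = None

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "inputs": {
                "genotypes": _sha256(config.genotypes),
                "metadata": _sha256(config.metadata),
                "occurrences": (_sha256(config.occurrences)
                                if config.occurrences else None),
            },
        }
        _write_json(manifest, out / "manifest.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return summary
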