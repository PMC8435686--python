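"""End-to-end analysis pipeline with deterministic artifacts.

Runs the full organ-diversity analysis from a single config, either on a
synthetic dataset or on user-supplied inputs (feature table TSV + MGF),
writing every intermediate and result artifact plus a manifest recording
versions, parameters, per-stage seeds and artifact SHA-256 hashes.
Reruns with an identical config are bit-identical.

Stage order: load/simulate -> similarity matrix -> molecular network ->
Sørensen + structural distance matrices -> organ partition + richness ->
rarefaction per organ -> PERMANOVAs (global, pairwise, per-species) ->
dispersion + variance partition -> classifier + Boruta -> LMMs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import phytodiv
from phytodiv import occurrence, spectra, structural, rarefaction as raref
from phytodiv import multivariate as mv
from phytodiv import classification as clf
from phytodiv import univariate as uv
from phytodiv.synthetic import SyntheticConfig, generate_dataset, write_truth, config_to_dict

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by labeled hashing of the master seed, so
    adding a stage never shifts the randomness of earlier stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` or (``table_path``, ``mgf_path``) must be
    given.  ``seed`` is the master seed; every stochastic stage uses a
    labeled seed derived from it.
    """

    output_dir: str | Path
    synthetic: SyntheticConfig | None = None
    table_path: str | Path | None = None
    mgf_path: str | Path | None = None
    similarity: spectra.SimilarityParams = field(default_factory=spectra.SimilarityParams)
    min_cosine: float = 0.7
    topk: int = 1000
    rarefaction_replicates: int = 5000
    n_permutations: int = 999
    classifier_trees: int = 2000
    boruta_trees: int = 500
    boruta_max_iterations: int = 100
    boruta_alpha: float = 0.01
    boruta_importance: str = "permutation"
    run_classification: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.table_path is not None or self.mgf_path is not None
        if self.synthetic is not None and has_files:
            raise ValueError("config must give either a synthetic block or "
                             "input paths, not both")
        if self.synthetic is None and (self.table_path is None or self.mgf_path is None):
            raise ValueError("config must give a synthetic block or both "
                             "table_path and mgf_path")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: stage_seed(config.seed, name) for name in
             ("synthetic", "rarefaction", "permanova", "pairwise",
              "per_species", "dispersion", "variance", "classifier", "boruta")}
    artifacts: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # ---- load or simulate
    if config.synthetic is not None:
        syn = SyntheticConfig(**{**config_to_dict(config.synthetic),
                                 "seed": seeds["synthetic"]})
        table, library, truth = _stage("simulate")(lambda: generate_dataset(syn))
        occurrence.write_feature_table(table, out / "feature_table.tsv")
        spectra.write_mgf(library, out / "spectra.mgf")
        write_truth(truth, out / "truth.json")
        artifacts["feature_table"] = out / "feature_table.tsv"
        artifacts["spectra"] = out / "spectra.mgf"
        artifacts["truth"] = out / "truth.json"
    else:
        table = _stage("load_table")(
            lambda: occurrence.read_feature_table(config.table_path))
        library = _stage("load_spectra")(lambda: spectra.read_mgf(config.mgf_path))

    meta = table.metadata

    # ---- spectral similarity and network
    eps = _stage("similarity")(
        lambda: spectra.build_similarity_matrix(library, config.similarity))
    spectra.write_similarity_matrix(eps, out / "epsilon.tsv")
    artifacts["epsilon"] = out / "epsilon.tsv"
    network = _stage("network")(
        lambda: spectra.build_network(eps, config.min_cosine, config.topk))
    spectra.write_edge_list(network, out / "network_edges.tsv")
    artifacts["network_edges"] = out / "network_edges.tsv"

    # ---- distance matrices
    d_occ = _stage("sorensen")(lambda: occurrence.sorensen_matrix(table))
    occurrence.write_distance_matrix(d_occ, out / "sorensen.tsv")
    artifacts["sorensen"] = out / "sorensen.tsv"
    d_str = _stage("structural")(
        lambda: structural.structural_dissimilarity_matrix(table, eps))
    occurrence.write_distance_matrix(d_str, out / "structural.tsv")
    artifacts["structural"] = out / "structural.tsv"

    # ---- occurrence partition and richness
    part = _stage("partition")(lambda: occurrence.organ_partition(table))
    part.to_json(out / "organ_partition.json")
    artifacts["organ_partition"] = out / "organ_partition.json"
    alpha = occurrence.alpha_richness(table)
    gamma = occurrence.gamma_richness(table, "organ")
    rich = pd.DataFrame({"alpha_richness": alpha,
                         "organ": meta["organ"], "species": meta["species"]})
    rich.to_csv(out / "alpha_richness.tsv", sep="\t", index_label="sample_id")
    gamma.to_csv(out / "gamma_richness.tsv", sep="\t", index_label="organ")
    artifacts["alpha_richness"] = out / "alpha_richness.tsv"
    artifacts["gamma_richness"] = out / "gamma_richness.tsv"

    # ---- rarefaction per organ
    raref_out = {}
    for i, organ in enumerate(sorted(set(meta["organ"]))):
        res = _stage(f"rarefaction:{organ}")(lambda o=organ, k=i: raref.fit_asymptote(
            raref.constrained_accumulation(
                table, o, n_replicates=config.rarefaction_replicates,
                seed=seeds["rarefaction"] + k)))
        raref_out[organ] = res.to_dict()
    _write_json(out / "rarefaction.json", raref_out)
    artifacts["rarefaction"] = out / "rarefaction.json"

    # ---- multivariate statistics on both matrices
    mv_out = {}
    for label, dm in (("occurrence", d_occ), ("structural", d_str)):
        global_tab = _stage(f"permanova:{label}")(lambda dmx=dm: mv.permanova(
            dmx, meta, ["organ", "species", "organ:species"], strata="plant",
            n_permutations=config.n_permutations, seed=seeds["permanova"]))
        _, pairwise = _stage(f"pairwise:{label}")(lambda dmx=dm: mv.pairwise_permanova(
            dmx, meta, "organ", n_permutations=config.n_permutations,
            seed=seeds["pairwise"]))
        per_species = {}
        for k, sp in enumerate(sorted(meta["species"].unique())):
            mask = (meta["species"] == sp).to_numpy()
            ids = [s for s, m in zip(dm.sample_ids, mask) if m]
            tab = _stage(f"per_species:{label}:{sp}")(lambda i=ids, m=mask: mv.permanova(
                dm.subset(i), meta.loc[m], ["organ"],
                n_permutations=config.n_permutations,
                seed=seeds["per_species"] + k))
            row = tab.term("organ")
            per_species[sp] = {"F": float(row["F"]), "p": float(row["p"]),
                               "R2": float(row["R2"])}
        disp = _stage(f"dispersion:{label}")(lambda dmx=dm: mv.dispersion(
            dmx, meta, "organ", n_permutations=config.n_permutations,
            seed=seeds["dispersion"]))
        vp = _stage(f"variance:{label}")(lambda dmx=dm: mv.variance_partition(
            dmx, meta, factor="species", subset_by="organ",
            n_permutations=config.n_permutations, seed=seeds["variance"]))
        mv_out[label] = {
            "permanova": global_tab.to_dict(),
            "pairwise": pairwise.to_dict(orient="records"),
            "per_species": per_species,
            "dispersion": disp.to_dict(),
            "variance_partition": [v.to_dict() for v in vp],
        }
    _write_json(out / "multivariate.json", mv_out)
    artifacts["multivariate"] = out / "multivariate.json"

    # ---- classification
    if config.run_classification:
        cls = _stage("classifier")(lambda: clf.fit_organ_classifier(
            table, n_trees=config.classifier_trees, seed=seeds["classifier"]))
        _write_json(out / "classifier.json", cls.to_dict())
        artifacts["classifier"] = out / "classifier.json"
        bres = _stage("boruta")(lambda: clf.boruta(
            table, max_iterations=config.boruta_max_iterations,
            alpha=config.boruta_alpha, n_trees=config.boruta_trees,
            importance=config.boruta_importance, seed=seeds["boruta"]))
        _write_json(out / "boruta.json", bres.to_dict())
        bres.to_frame().to_csv(out / "boruta_decisions.tsv", sep="\t", index=False)
        artifacts["boruta"] = out / "boruta.json"
        artifacts["boruta_decisions"] = out / "boruta_decisions.tsv"

    # ---- mixed models on richness and structural complexity
    complexity = pd.Series(
        {r.sample_id: r.complexity for r in structural.complexity_records(table, eps)},
        name="complexity").loc[meta.index]
    lmm_out = {}
    for label, resp in (("richness", alpha.astype(float)), ("complexity", complexity)):
        res = _stage(f"lmm:{label}")(lambda r=resp, lb=label: uv.fit_diversity_lmm(
            r, meta, test_term="organ:species", response_name=lb))
        _, letters, lrts = _stage(f"lmm_followup:{label}")(
            lambda r=resp: uv.per_species_organ_contrasts(r, meta))
        lmm_out[label] = {
            "interaction": res.to_dict(),
            "per_species": {sp: {"chi2": l.chi2, "df": l.df, "p": l.p}
                            for sp, l in lrts.items()},
            "letters": letters,
        }
    _write_json(out / "lmm.json", lmm_out)
    artifacts["lmm"] = out / "lmm.json"

    manifest = {
        "phytodiv_version": phytodiv.__version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "similarity": {
                "fragment_tol": config.similarity.fragment_tol,
                "precursor_tol": config.similarity.precursor_tol,
                "min_matched_peaks": config.similarity.min_matched_peaks,
                "intensity_transform": config.similarity.intensity_transform,
            },
            "min_cosine": config.min_cosine,
            "topk": config.topk,
            "rarefaction_replicates": config.rarefaction_replicates,
            "n_permutations": config.n_permutations,
            "classifier_trees": config.classifier_trees,
            "boruta": {
                "trees": config.boruta_trees,
                "max_iterations": config.boruta_max_iterations,
                "alpha": config.boruta_alpha,
                "importance": config.boruta_importance,
            },
            "synthetic": (config_to_dict(config.synthetic)
                          if config.synthetic is not None else None),
        },
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
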