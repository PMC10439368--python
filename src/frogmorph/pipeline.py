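"""End-to-end analysis pipeline: from measurement table + tree to a report bundle.

Stages, in order: read and validate → derive structural totals →
Mosimann size correction → pPCA (full log-shape data, Brownian
covariance) and SPCA with ratio/allometry spectra (both variable sets) →
PERMANOVA with pairwise contrasts for the three groupings → PGLS model
selection on PC1/PC2 → LDA and pFDA for the three groupings (the
"Neobatrachia" species are withheld from clade training and predicted as
held-out tips) → case-wise reports → ancestral states of PC1/PC2.

All randomness flows from one root seed, split per stage with
`numpy.random.SeedSequence(seed).spawn(...)` in a fixed stage order, so a
stage rerun with its recorded seed matches the full run and identical
(config, seed) reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discriminant as da
from . import inference, morphometrics as mm, ordination as ord_
from . import phylo as ph

__all__ = ["AnalysisConfig", "ReportBundle", "run_full", "load_config"]

_STAGES = (
    "descriptives", "ppca", "spca", "spectra",
    "permanova", "pgls", "discriminant", "ancestral",
)


@dataclass
class AnalysisConfig:
    measurements: str
    tree: str
    output_dir: str
    composition: dict | None = None
    n_perm: int = 999
    n_boot: int = 999
    ci: float = 0.68
    lambda_grid_step: float = 0.01
    priors: str = "proportional"
    adjust: str = "bonferroni"
    coding: str = "integer"
    seed: int = 0
    locomotor_levels: tuple = tuple(mm.LOCOMOTOR_MODES)
    habitat_levels: tuple = tuple(mm.HABITATS)
    clade_levels: tuple = ("basal", "Hyloidea", "Ranoidea")
    holdout_clade: str = "Neobatrachia"

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return AnalysisConfig(**raw)


@dataclass
class ReportBundle:
    config: AnalysisConfig
    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        self.artifacts[name] = path

    def write_manifest(self) -> Path:
        manifest = {
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "artifacts": {
                name: {
                    "path": p.name,
                    "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                }
                for name, p in sorted(self.artifacts.items())
            },
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _write_csv(bundle: ReportBundle, name: str, frame: pd.DataFrame, **kw) -> None:
    path = bundle.out_dir / f"{name}.csv"
    frame.to_csv(path, float_format="%.10g", **kw)
    bundle.add(name, path)


def _write_json(bundle: ReportBundle, name: str, obj: dict) -> None:
    path = bundle.out_dir / f"{name}.json"
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    bundle.add(name, path)


def run_full(config: AnalysisConfig) -> ReportBundle:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(config, out_dir)
    stage_seeds = {
        name: s for name, s in zip(
            _STAGES,
            [int(c.generate_state(1)[0] % (2**31 - 1))
             for c in np.random.SeedSequence(config.seed).spawn(len(_STAGES))],
        )
    }

    # ---- read & validate -------------------------------------------------
    stage = "read"
    try:
        table = mm.read_measurements(config.measurements)
        tree = ph.read_newick(Path(config.tree).read_text())
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    tips = set(tree.tip_labels)
    species = table.species
    missing = sorted(set(species) - tips)
    if missing:
        raise PipelineError(stage, f"tree lacks measurement species: {missing}")
    if tips - set(species):
        tree = ph.prune_to_taxa(tree, species)
    bundle.log.append(
        f"read: {table.n} species x {len(table.measurement_columns())} measurements; "
        f"tree pruned to {tree.n_tips} tips"
    )

    groupings = {
        "locomotor_mode": list(config.locomotor_levels),
        "habitat": list(config.habitat_levels),
        "phylo_group": list(config.clade_levels) + [config.holdout_clade],
    }

    # ---- derive + size-correct ------------------------------------------
    structural = mm.derive_structural(table, config.composition)
    shape_full = mm.mosimann_shape(table, log=True)
    shape_struct = mm.mosimann_shape(structural, log=True)
    ratios = mm.compute_ratios(mm.with_totals(table, config.composition))

    for grouping, levels in groupings.items():
        exclude = (config.holdout_clade,) if grouping == "phylo_group" else ()
        values = pd.concat(
            [shape_full.as_ratio().values, ratios,
             table.data[["iliac_angle"]]], axis=1
        )
        present = set(table.labels(grouping))
        summ = mm.group_summary(
            values, table.labels(grouping), grouping,
            level_order=[l for l in levels if l not in exclude and l in present],
            exclude=exclude,
        )
        _write_json(bundle, f"descriptives_{grouping}", summ.to_record())
    bundle.log.append("descriptives: 3 groupings summarized")

    # ---- ordination ------------------------------------------------------
    tip_order = species
    cov = ph.brownian_covariance(tree, tip_order=tip_order)
    Xfull = shape_full.values.loc[tip_order].to_numpy()
    pp = ord_.ppca(Xfull, cov, variables=shape_full.variable_set,
                   species=tip_order)
    _write_csv(bundle, "ppca_scores", pp.scores_frame(), index_label="species_id")
    _write_csv(bundle, "ppca_loadings", pp.loadings_frame(), index_label="variable")
    _write_csv(
        bundle, "ppca_eigenvalues",
        pd.DataFrame({"eigenvalue": pp.eigenvalues,
                      "percent_variance": pp.percent_variance}),
        index_label="axis",
    )
    bundle.results["ppca"] = pp

    logY_full = np.log(table.matrix(shape_full.variable_set))
    logY_struct = np.log(structural.matrix(shape_struct.variable_set))
    sp_full = ord_.spca(logY_full, variables=shape_full.variable_set,
                        species=species)
    sp_struct = ord_.spca(logY_struct, variables=shape_struct.variable_set,
                          species=species)
    for name, res in (("full", sp_full), ("structural", sp_struct)):
        _write_csv(bundle, f"spca_{name}_scores", res.scores_frame(),
                   index_label="species_id")
        _write_csv(bundle, f"spca_{name}_loadings", res.loadings_frame(),
                   index_label="variable")
        _write_csv(
            bundle, f"spca_{name}_eigenvalues",
            pd.DataFrame({"eigenvalue": res.eigenvalues,
                          "percent_variance": res.percent_variance}),
            index_label="axis",
        )
    bundle.results["spca_full"] = sp_full
    bundle.results["spca_structural"] = sp_struct
    bundle.log.append(
        f"ordination: pPCA PC1 {pp.percent_variance[0]:.1f}%; "
        f"SPCA full PC1 {sp_full.percent_variance[0]:.1f}%, "
        f"structural PC1 {sp_struct.percent_variance[0]:.1f}%"
    )

    # ---- spectra ---------------------------------------------------------
    rng = np.random.default_rng(stage_seeds["spectra"])
    for name, Y, vars_ in (("full", logY_full, shape_full.variable_set),
                           ("structural", logY_struct, shape_struct.variable_set)):
        for axis in (0, 1):
            spec = ord_.ratio_spectrum(
                Y, axis=axis, n_boot=config.n_boot, ci=config.ci,
                seed=rng, variables=vars_,
            )
            _write_csv(bundle, f"spectrum_{name}_pc{axis + 1}", spec.frame(),
                       index_label="variable")
            bundle.results[f"spectrum_{name}_pc{axis + 1}"] = spec
        allo = ord_.allometry_spectrum(
            Y, n_boot=config.n_boot, ci=config.ci, seed=rng, variables=vars_,
        )
        _write_csv(bundle, f"allometry_{name}", allo.frame(),
                   index_label="variable")
        bundle.results[f"allometry_{name}"] = allo
    bundle.log.append("spectra: PC1/PC2 + allometry for both variable sets")

    # ---- PERMANOVA -------------------------------------------------------
    rng = np.random.default_rng(stage_seeds["permanova"])
    X_shape = shape_full.values.to_numpy()
    for grouping, levels in groupings.items():
        labels = table.labels(grouping)
        keep = ~labels.isin([config.holdout_clade]) if grouping == "phylo_group" \
            else pd.Series(True, index=labels.index)
        counts = labels[keep].value_counts()
        singletons = [g for g in counts.index if counts[g] < 2]
        if singletons:
            bundle.log.append(
                f"permanova {grouping}: dropping singleton group(s) {singletons}"
            )
            keep &= ~labels.isin(singletons)
        res = inference.pairwise_permanova(
            X_shape[keep.to_numpy()], labels[keep].tolist(),
            n_perm=config.n_perm, adjust=config.adjust, seed=rng,
            grouping=grouping,
        )
        out = res.pairwise.copy()
        out.loc[len(out)] = ["overall", res.pseudo_f, res.r_squared, res.p_value,
                             res.p_value]
        _write_csv(bundle, f"permanova_{grouping}", out, index=False)
        bundle.results[f"permanova_{grouping}"] = res
    bundle.log.append("permanova: 3 groupings with pairwise contrasts")

    # ---- PGLS ------------------------------------------------------------
    scores = pp.scores_frame()
    labels_lm = table.data.loc[tip_order, "locomotor_mode"]
    labels_hab = table.data.loc[tip_order, "habitat"]
    level_orders = {"locomotor_mode": list(config.locomotor_levels),
                    "habitat": list(config.habitat_levels)}
    candidates = {
        "LM": pd.DataFrame({"locomotor_mode": labels_lm}),
        "Habitat": pd.DataFrame({"habitat": labels_hab}),
        "LM+Habitat": pd.DataFrame({"locomotor_mode": labels_lm,
                                    "habitat": labels_hab}),
    }
    for pc in ("PC1", "PC2"):
        fits = inference.select_model(
            scores[pc].to_numpy(), candidates, cov, response=pc,
            coding=config.coding, level_orders=level_orders,
            grid_step=config.lambda_grid_step,
        )
        rows = [{"model": f.design_description, "lambda": f.lam,
                 "logLik": f.log_likelihood, "AIC": f.aic,
                 "best": i == 0} for i, f in enumerate(fits)]
        _write_csv(bundle, f"pgls_selection_{pc.lower()}",
                   pd.DataFrame(rows), index=False)
        _write_csv(bundle, f"pgls_best_{pc.lower()}", fits[0].coefficients,
                   index_label="term")
        bundle.results[f"pgls_{pc.lower()}"] = fits
    bundle.log.append("pgls: model selection on PC1/PC2")

    # ---- discriminant ----------------------------------------------------
    # log-shape rows sum to 0, so discriminants run in an orthonormal
    # basis of shape space (affine-invariant; avoids a singular pooled cov)
    H = ord_.isometry_basis(len(shape_full.variable_set))
    X_da = shape_full.values.loc[tip_order].to_numpy() @ H
    da_vars = tuple(f"shape{j + 1}" for j in range(H.shape[1]))
    alt = table.data.loc[tip_order, "locomotor_mode_2"] \
        if "locomotor_mode_2" in table.data.columns else None
    proxy = table.data.loc[tip_order, "proxy_label"] \
        if "proxy_label" in table.data.columns else None
    for grouping, levels in groupings.items():
        labels = table.data.loc[tip_order, grouping]
        if grouping == "phylo_group":
            train_mask = (labels != config.holdout_clade).to_numpy()
            train_levels = list(config.clade_levels)
        else:
            train_mask = np.ones(len(labels), dtype=bool)
            train_levels = [l for l in levels if (labels == l).any()]
        counts = labels[train_mask].value_counts()
        singletons = [g for g in train_levels if counts.get(g, 0) < 2]
        if singletons:
            bundle.log.append(
                f"discriminant {grouping}: dropping singleton class(es) {singletons}"
            )
            train_mask &= ~labels.isin(singletons).to_numpy()
            train_levels = [l for l in train_levels if l not in singletons]
        train_species = [s for s, m in zip(tip_order, train_mask) if m]
        Xtr = X_da[train_mask]
        ytr = labels[train_mask]
        cov_tr = ph.brownian_covariance(
            ph.prune_to_taxa(tree, train_species), tip_order=train_species
        )

        lda = da.lda_fit(Xtr, ytr, priors=config.priors, levels=train_levels,
                         variables=da_vars)
        preds_lda = da.predict(
            lda, Xtr, species=train_species, true_labels=ytr.tolist(),
            alt_labels=(alt[train_mask].tolist()
                        if alt is not None and grouping == "locomotor_mode" else None),
            proxy_flags=(proxy[train_mask].tolist()
                         if proxy is not None and grouping == "locomotor_mode" else None),
        )
        cm_lda = da.confusion(ytr.tolist(), [p.predicted for p in preds_lda],
                              levels=train_levels)

        pfda = da.pfda_fit(Xtr, ytr, cov_tr, lam="optimal",
                           priors=config.priors, levels=train_levels,
                           variables=da_vars)
        preds_pfda = da.predict(
            pfda, Xtr, species=train_species, true_labels=ytr.tolist(),
            alt_labels=(alt[train_mask].tolist()
                        if alt is not None and grouping == "locomotor_mode" else None),
            proxy_flags=(proxy[train_mask].tolist()
                         if proxy is not None and grouping == "locomotor_mode" else None),
        )
        cm_pfda = da.confusion(ytr.tolist(), [p.predicted for p in preds_pfda],
                               levels=train_levels)

        for tag, cm, model, preds in (
            ("lda", cm_lda, lda, preds_lda),
            ("pfda", cm_pfda, pfda, preds_pfda),
        ):
            _write_csv(bundle, f"{tag}_{grouping}_confusion_counts", cm.counts,
                       index_label="true")
            _write_csv(bundle, f"{tag}_{grouping}_confusion_percent",
                       cm.row_percent.round(1), index_label="true")
            _write_json(bundle, f"{tag}_{grouping}_model", {
                "method": model.method,
                "accuracy_percent": cm.accuracy,
                "lambda": model.lam,
                "priors": {g: float(p) for g, p in zip(model.levels, model.priors)},
                "proportion_of_trace": model.proportion_of_trace.tolist(),
            })
            case = pd.DataFrame(
                [{"species_id": p.species_id, "true": p.true_label,
                  "predicted": p.predicted, "correct": p.correct,
                  "matches_alternative": p.matches_alternative,
                  **{f"post_{g}": p.posterior[g] for g in model.levels}}
                 for p in preds]
            )
            _write_csv(bundle, f"{tag}_{grouping}_casewise", case, index=False)
            bundle.results[f"{tag}_{grouping}"] = (model, cm, preds)

        if grouping == "locomotor_mode":
            _write_json(bundle, "casewise_agreement", da.casewise_report(
                preds_lda, comparison=preds_pfda))

        if grouping == "phylo_group" and (~train_mask).any():
            held_species = [s for s, m in zip(tip_order, train_mask) if not m]
            X_held = X_da[~train_mask]
            cov_full = ph.brownian_covariance(tree, tip_order=tip_order)
            held_lda = da.predict(lda, X_held, species=held_species)
            held_pfda = da.predict_unlabeled_tips(
                pfda, X_held, held_species, cov_full, Xtr, species=held_species,
            )
            held = pd.DataFrame(
                [{"species_id": a.species_id, "lda": a.predicted,
                  "pfda": b.predicted}
                 for a, b in zip(held_lda, held_pfda)]
            )
            _write_csv(bundle, "neobatrachia_predictions", held, index=False)
            bundle.results["neobatrachia"] = (held_lda, held_pfda)
    bundle.log.append("discriminant: LDA + pFDA for 3 groupings")

    # ---- ancestral states ------------------------------------------------
    for pc in ("PC1", "PC2"):
        vals = {s: float(v) for s, v in scores[pc].items()}
        anc = ph.ancestral_states(tree, vals)
        frame = pd.DataFrame(
            sorted(anc.items()), columns=["node", pc]
        ).set_index("node")
        _write_csv(bundle, f"ancestral_states_{pc.lower()}", frame)
    bundle.log.append("ancestral: PC1/PC2 states reconstructed")

    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(bundle.log) + "\n")
    bundle.add("run_log", log_path)
    bundle.write_manifest()
    return bundle
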