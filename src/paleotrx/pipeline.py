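"""End-to-end orchestration with reproducibility metadata.

A run configuration (plain JSON) names the inputs and thresholds; ``run``
executes the stages in dependency order — encode, model selection, ML
tree inference with branch supports, topology tests against the species
tree, ancestral reconstruction, joint extant+ancestral clustering, and
(when reference/bulk tables are given) deconvolution — writing each
stage's outputs plus a manifest with input checksums, derived seeds, and
the package version into the run directory.

One master seed is expanded into independent per-stage seeds by hashing
the stage name with the master seed (a splitmix-style derivation), so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

import paleotrx
from paleotrx import asr as asr_mod
from paleotrx import clustering, data_io, deconv, substmodel, topotests, treelik

#: support thresholds used to flag a branch as highly supported
SUPPORT_THRESHOLDS = {
    "stdboot": 0.80,
    "sh_alrt": 80.0,
    "abayes": 0.90,
    "param_alrt": 0.95,
    "lboot": 0.90,
}


@dataclass
class RunConfig:
    """Validated run configuration."""

    out_dir: str
    expression: str | None = None
    matrix: str | None = None
    species_tree: str | None = None
    reference: str | None = None
    bulk: str | None = None
    model: str = "GTR2+FO+R3"
    model_candidates: list[str] | None = None
    tpm_threshold: float = 2.0
    confidence_level: float = 0.05
    k_range: list[int] = field(default_factory=lambda: [2, 9])
    fold: float = 5.0
    min_expression: float = 2.0
    tau: float = 0.005
    seed: int = 0
    nni_starts: int = 5
    bootstrap_replicates: int = 0
    rell_replicates: int = 10000
    run_topotests: bool = True
    run_asr: bool = True
    run_clustering: bool = True

    def validate(self) -> None:
        if self.expression is None and self.matrix is None:
            raise ValueError("config needs 'expression' or 'matrix'")
        for key in ("expression", "matrix", "species_tree", "reference", "bulk"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path for {key!r} does not exist: {p}")
        if self.tpm_threshold <= 0:
            raise ValueError("tpm_threshold must be positive")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0,1)")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("k_range must be [lo, hi] with 2 <= lo <= hi")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def derive_seed(master: int, stage: str) -> int:
    """Per-stage seed from the master seed and stage name (stable hash)."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": paleotrx.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }
    for key in ("expression", "matrix", "species_tree", "reference", "bulk"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _checksum(p)}

    # -- stage: encode -----------------------------------------------------
    if config.expression is not None:
        expr = data_io.read_expression_tsv(config.expression)
        bm = data_io.encode_binary(expr, threshold=config.tpm_threshold)
        data_io.write_matrix(bm, out / "matrix.nex")
        manifest["stages"]["encode"] = {
            "threshold": config.tpm_threshold,
            "n_taxa": bm.n_taxa,
            "n_genes": bm.n_genes,
        }
    else:
        bm = data_io.read_matrix(config.matrix)

    species_tree = None
    if config.species_tree is not None:
        species_tree = data_io.read_tree(config.species_tree)
    elif bm.tree is not None:
        species_tree = bm.tree

    # -- stage: model selection --------------------------------------------
    guide = species_tree
    if guide is None:
        guide, _ = treelik.nni_search(
            bm,
            substmodel.model_from_spec("EQ"),
            random_starts=1,
            seed=derive_seed(config.seed, "guide"),
        )
    if config.model_candidates:
        rows = substmodel.model_select(bm, guide, config.model_candidates)
        best = rows[0]
        model = best.model
        manifest["stages"]["model_select"] = {
            "table": [
                {"spec": r.spec, "loglik": r.loglik, "k": r.k_params, "aicc": r.aicc}
                for r in rows
            ],
            "selected": best.spec,
        }
    else:
        start = substmodel.model_from_spec(config.model)
        _, model, lnl, _ = substmodel.fit_joint(bm, guide.copy(), start)
        manifest["stages"]["model_fit"] = {"spec": config.model, "loglik": lnl}
    (out / "model.json").write_text(model.to_json())

    # -- stage: ML tree + supports ------------------------------------------
    # warm-start the climb from the guide tree (plus random starts when no
    # species tree constrains the guide)
    ml_tree, ml_lnl = treelik.nni_search(
        bm,
        model,
        start_tree=guide if species_tree is not None else None,
        random_starts=config.nni_starts,
        seed=derive_seed(config.seed, "nni"),
    )
    data_io.write_tree(ml_tree, out / "ml_tree.nwk")
    manifest["stages"]["infer"] = {"loglik": ml_lnl, "starts": config.nni_starts}
    support = treelik.single_branch_tests(
        ml_tree, bm, model,
        rell_replicates=config.rell_replicates,
        seed=derive_seed(config.seed, "alrt"),
    )
    if config.bootstrap_replicates > 0:
        boot = treelik.standard_bootstrap(
            bm, model, ml_tree,
            replicates=config.bootstrap_replicates,
            seed=derive_seed(config.seed, "boot"),
        )
        support = support.merge(boot)
    support.table().to_csv(out / "support.tsv", sep="\t", index=False)

    # -- stage: topology tests ----------------------------------------------
    if config.run_topotests and species_tree is not None:
        sl = topotests.site_loglik_matrix([ml_tree, species_tree], bm, model)
        res = topotests.run_tests(
            sl,
            replicates=config.rell_replicates,
            seed=derive_seed(config.seed, "topotest"),
        )
        res.table.insert(0, "tree", ["ml_tree", "species_tree"])
        res.table.to_csv(out / "topotests.tsv", sep="\t", index=False)
        manifest["stages"]["topotests"] = {
            "replicates": config.rell_replicates,
            "species_tree_in_au_ci": bool(
                res.table.p_au[1] >= config.confidence_level
            ),
        }

    # -- stage: ancestral reconstruction ------------------------------------
    ar = None
    if config.run_asr and species_tree is not None:
        ar = asr_mod.marginal_posteriors(species_tree, bm, model)
        asr_mod.write_posteriors_tsv(ar, out / "ancestral_posteriors.tsv")
        joint = asr_mod.ancestral_transcriptomes(ar)
        data_io.write_matrix(joint, out / "joint.nex")
        manifest["stages"]["asr"] = {"n_nodes": len(ar.node_ids)}

    # -- stage: clustering ----------------------------------------------------
    if config.run_clustering:
        target = joint if ar is not None else bm
        filt, report = data_io.filter_columns(target)
        m = clustering.estimate_fuzzifier(filt.n_taxa, filt.n_genes)
        lo, hi = config.k_range
        hi = min(hi, filt.n_taxa - 1)
        table = clustering.select_k(
            filt.states.astype(float),
            filt.taxa,
            range(lo, hi + 1),
            m=m,
            seed=derive_seed(config.seed, "fcm"),
        )
        table.to_csv(out / "k_selection.tsv", sep="\t", index=False)
        best_k = int(table.loc[table.elbow.idxmax(), "K"]) if table.elbow.notna().any() else lo
        res = clustering.fcm(
            filt.states.astype(float), filt.taxa, best_k, m,
            seed=derive_seed(config.seed, "fcm_final"),
        )
        res.membership_frame().to_csv(out / "memberships.tsv", sep="\t")
        manifest["stages"]["clustering"] = {
            "fuzzifier": m,
            "K": best_k,
            "filtered_genes": filt.n_genes,
            **report,
        }

    # -- stage: deconvolution -------------------------------------------------
    if config.reference is not None and config.bulk is not None:
        ref = data_io.read_expression_tsv(config.reference)
        bulk = data_io.read_expression_tsv(config.bulk)
        sig = deconv.build_signature(
            ref, expression_threshold=config.min_expression, fold=config.fold
        )
        mf = deconv.deconvolve(bulk, sig)
        mf.to_frame().to_csv(out / "fractions.tsv", sep="\t")
        manifest["stages"]["deconv"] = {
            "markers": len(sig.marker_gene_ids),
            "tau": config.tau,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
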