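"""End-to-end orchestration: simulate -> measure -> stats -> cluster -> classify -> PCA.

A single top-level seed fans out into named substreams (one per stochastic
stage), so adding a stage never shifts another stage's randomness and a
fixed-seed run is byte-reproducible. Every statistic in the report is
recomputable from the persisted intermediate files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, stats, synthetic
from .morphometrics import DESCRIPTOR_NAMES

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_features",
    "run_full",
    "stage_seed",
    "write_features",
]

CANONICAL_COLUMNS: tuple[str, ...] = ("cell_id", "roi") + DESCRIPTOR_NAMES


class SchemaError(ValueError):
    pass


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed from the top-level seed (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "gliamorph_run"
    features_path: str | None = None  # measure/simulate skipped when given
    pixel_size_um: float = 0.081
    n_cells_per_group: int = 80
    mmi_threshold: float = 0.55
    hca_k: int = 4
    lda_predictors: tuple[str, ...] = models.LDA_PREDICTORS
    train_frac: float = 0.7
    n_permutations: int = 999
    pca_permutations: int = 1000
    n_bootstrap: int = 1000
    alpha: float = 0.05

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "lda_predictors" in data:
            data["lda_predictors"] = tuple(data["lda_predictors"])
        return cls(**data)


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a feature table as CSV in the canonical column order."""
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    extra = [c for c in table.columns if c not in CANONICAL_COLUMNS]
    table[list(CANONICAL_COLUMNS) + extra].to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Load a feature CSV, validating and canonicalizing the header.

    Columns may appear in any order; unknown columns are preserved after
    the canonical ones. Missing canonical columns raise ``SchemaError``
    listing the absent names.
    """
    table = pd.read_csv(path)
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature file {path} missing columns: {missing}")
    extra = [c for c in table.columns if c not in CANONICAL_COLUMNS]
    return table[list(CANONICAL_COLUMNS) + extra]


def run_full(config: RunConfig) -> dict:
    """Execute the whole analysis and persist intermediates plus a report.

    Stages: feature acquisition (simulation from the published group
    statistics unless ``features_path`` points at a measured table),
    z-scoring, MMI feature screening, group statistics (Kruskal-Wallis /
    Dunn and PERMANOVA), Ward/Manhattan clustering with branch identities
    and minority-cell exclusion, LDA on the selected predictors with Wilks'
    test, and permutation-tested PCA on the remaining descriptors.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.features_path is not None:
        table = read_features(config.features_path)
    else:
        specs = [
            dataclasses.replace(s, n_cells=config.n_cells_per_group)
            for s in synthetic.GROUP_SPECS_TABLE1.values()
        ]
        table = synthetic.generate_feature_table(
            specs, seed=stage_seed(config.seed, "simulate")
        )
    write_features(table, out / "features.csv")
    report: dict = {
        "config": json.loads(config.to_json()),
        "n_cells": int(len(table)),
    }

    ztable = stats.zscore_table(table)

    selected, mmi_scores = stats.select_multimodal(table, threshold=config.mmi_threshold)
    report["mmi"] = {k: float(v) for k, v in mmi_scores.items()}
    report["mmi_selected"] = selected
    corr = stats.pearson_matrix(table, selected) if len(selected) >= 2 else None
    if corr is not None:
        corr.to_csv(out / "mmi_correlations.csv")

    kw = {}
    sig_rows = []
    for c in DESCRIPTOR_NAMES:
        h, df, p, pairs = stats.kruskal_dunn(table[c].to_numpy(), table["roi"].to_numpy())
        kw[c] = {"H": h, "df": df, "p": p}
        for _, row in pairs.iterrows():
            sig_rows.append({
                "parameter": c, "group_a": row["group_a"], "group_b": row["group_b"],
                "p_adj": row["p_adj"],
            })
    report["kruskal_wallis"] = kw
    # per-parameter pairwise significance matrix (Dunn, Bonferroni-adjusted)
    pd.DataFrame(sig_rows).pivot(
        index="parameter", columns=["group_a", "group_b"], values="p_adj"
    ).to_csv(out / "significance_matrix.csv")

    perm = stats.permanova(
        ztable, "roi", n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "permanova"),
    )
    report["permanova"] = {
        "pseudo_F": perm.pseudo_F,
        "df_between": perm.df_between,
        "p": perm.p_value,
        "pairwise": perm.pairwise.to_dict(orient="records"),
    }

    tree = models.hca_ward_manhattan(ztable)
    cut = models.cut_and_identify(tree, config.hca_k, table["roi"].to_numpy())
    clusters = {
        "k": config.hca_k,
        "identity": {str(k): v for k, v in cut.identity.items()},
        "composition": cut.composition.to_dict(),
        "cluster_sizes": {str(k): int(v) for k, v in cut.cluster_sizes.items()},
        "n_minority_excluded": int(cut.minority_cells.size),
        "ambiguous": cut.ambiguous,
    }
    (out / "clusters.json").write_text(json.dumps(clusters, indent=2))
    report["clustering"] = clusters

    keep = np.setdiff1d(np.arange(len(table)), cut.minority_cells)
    filtered = table.iloc[keep].reset_index(drop=True)
    identities = np.array([cut.identity[c] for c in cut.labels[keep]])

    lda = models.lda_train_test(
        filtered, identities, predictors=config.lda_predictors,
        train_frac=config.train_frac, seed=stage_seed(config.seed, "lda"),
    )
    lam, chi2, df, pval = models.wilks_test(lda)
    lda_block = {
        "predictors": list(lda.predictors),
        "n_axes": lda.n_axes,
        "train_n": lda.train_n,
        "test_n": lda.test_n,
        "accuracy": lda.accuracy,
        "proportion_of_trace": lda.proportion_of_trace.tolist(),
        "coefficients": lda.coefficients.tolist(),
        "wilks_lambda": lam,
        "chi_squared": chi2,
        "df": df,
        "p": pval,
    }
    (out / "lda.json").write_text(json.dumps(lda_block, indent=2))
    report["lda"] = lda_block

    pca_params = [c for c in DESCRIPTOR_NAMES if c not in config.lda_predictors]
    pca = models.pca_permutation(
        filtered, pca_params, n_permutations=config.pca_permutations,
        n_bootstrap=config.n_bootstrap, seed=stage_seed(config.seed, "pca"),
        alpha=config.alpha,
    )
    pca_block = {
        "parameters": list(pca.parameters),
        "percent_variance": pca.percent_variance.tolist(),
        "percent_ci": pca.percent_ci.tolist(),
        "significant_pcs": pca.significant_pcs,
        "index_loadings_pc1": dict(
            zip(pca.parameters, pca.index_loadings[:, 0].tolist())
        ),
    }
    (out / "pca.json").write_text(json.dumps(pca_block, indent=2))
    report["pca"] = pca_block

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
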