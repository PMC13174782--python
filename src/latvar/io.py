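"""Tabular I/O, run manifests, and the end-to-end report pipeline.

The on-disk cohort schema is a UTF-8 TSV/CSV with columns exactly
``participant_id, tract, metric, hemisphere, value`` and ``NA`` for missing
values.  ``read_cohort`` validates hard invariants (no duplicate keys, no
negative values, whole-tract missingness) and reports offending rows.

``run_report`` chains the full pipeline — lateralisation indices, Bayesian
lateralisation table, VI permutation family, manifold embedding and
clusterability — and emits a manifest sufficient to regenerate every number
bit-identically (tool version, config digest, master seed, per-stage
substream keys, input digests).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import PriorSpec, bayes_table
from .indices import (COHORT_COLUMNS, HEMISPHERES, METRICS, SchemaError,
                      TRACTS, assemble_li_matrix, li_matrix_to_long)
from .manifold import clusterability, embed_phenotypes
from .permutation import vi_family_analysis, vi_results_frame
from .synthetic import SyntheticConfig, config_to_dict, generate_cohort

log = logging.getLogger("latvar")

#: Per-stage SeedSequence keys derived from the master seed:
#: SeedSequence([master, STAGE_STREAMS[stage]]).
STAGE_STREAMS = {"simulate": 101, "vi": 102, "embed": 103, "clusterability": 104}

_FLOAT_FMT = "%.17g"


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype={"participant_id": str},
                     na_values=["NA"], keep_default_na=True)
    if list(df.columns) != list(COHORT_COLUMNS):
        raise SchemaError(f"expected columns {list(COHORT_COLUMNS)}, "
                          f"got {list(df.columns)}")
    bad_tract = ~df["tract"].isin(TRACTS)
    if bad_tract.any():
        raise SchemaError(f"unknown tract at rows {_rows(df, bad_tract)}")
    bad_metric = ~df["metric"].isin(METRICS)
    if bad_metric.any():
        raise SchemaError(f"unknown metric at rows {_rows(df, bad_metric)}")
    bad_hemi = ~df["hemisphere"].isin(HEMISPHERES)
    if bad_hemi.any():
        raise SchemaError(f"unknown hemisphere at rows {_rows(df, bad_hemi)}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    neg = df["value"] < 0
    if neg.any():
        raise SchemaError(f"negative values at rows {_rows(df, neg)}")
    key_cols = ["participant_id", "tract", "metric", "hemisphere"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        keys = df.loc[dup, key_cols].drop_duplicates().to_records(index=False)
        raise SchemaError(f"duplicate (participant, tract, metric, hemisphere) "
                          f"key(s): {list(keys)[:5]} (rows {_rows(df, dup)})")
    # whole-tract missingness: within a participant/tract/hemisphere, the
    # three metrics must be jointly present or jointly missing
    miss = (df.assign(missing=df["value"].isna())
              .groupby(["participant_id", "tract", "hemisphere"])["missing"]
              .agg(["sum", "count"]))
    partial = miss[(miss["sum"] > 0) & (miss["sum"] < miss["count"])]
    if not partial.empty:
        raise SchemaError("partial-metric missingness (a failed reconstruction "
                          f"must drop all metrics together): {list(partial.index)[:5]}")
    return df


def _rows(df, mask):
    return list(df.index[mask][:10] + 2)  # 1-based, after the header line


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=_sep(path), index=False, na_rep="NA",
                 float_format=_FLOAT_FMT)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index=False, na_rep="NA",
              float_format=_FLOAT_FMT)


def _digest(obj) -> str:
    if isinstance(obj, (str, Path)) and Path(obj).is_file():
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def build_manifest(seed: int, config=None, inputs=(), command=None) -> dict:
    """Reproducibility manifest for one pipeline run."""
    return {
        "tool": "latvar",
        "version": __version__,
        "command": command if command is not None else " ".join(sys.argv),
        "master_seed": int(seed),
        "stage_streams": dict(STAGE_STREAMS),
        "config_digest": None if config is None else _digest(config),
        "input_digests": {str(p): _digest(p) for p in inputs},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [int(master), STAGE_STREAMS[stage]]).generate_state(1)[0] % (2 ** 31))


def run_report(cohort_path=None, config: SyntheticConfig | None = None, *,
               seed: int = 0, out_dir, n_perm: int = 10_000,
               prior: PriorSpec | None = None, n_neighbors: int = 15,
               min_dist: float = 0.1, exclusion_policy: str = "listwise") -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Stages, mirroring the analysis narrative: lateralisation (li.tsv,
    bayes.tsv) -> variability (vi_results.tsv) -> phenotypes
    (embedding.tsv, clusterability.json), plus manifest.json.  Returns the
    mapping of stage names to file paths; raises on any stage failure.
    """
    if (cohort_path is None) == (config is None):
        raise ValueError("provide exactly one of cohort_path or config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if config is not None:
        config = dataclasses.replace(config, seed=_stage_seed(seed, "simulate"))
        log.info("simulating cohort: n=%d", config.n_participants)
        table = generate_cohort(config)
        paths["cohort"] = out / "cohort.tsv"
        write_cohort(table, paths["cohort"])
        config_digest_src = config_to_dict(config)
    else:
        table = read_cohort(cohort_path)
        config_digest_src = None

    log.info("assembling LI matrix (policy=%s)", exclusion_policy)
    li = assemble_li_matrix(table, exclusion_policy="per_feature")
    li_complete = assemble_li_matrix(table, exclusion_policy=exclusion_policy)
    dropped = set(li.index) - set(li_complete.index)
    if dropped:
        log.info("excluded %d participant(s) with incomplete reconstructions",
                 len(dropped))
    paths["li"] = out / "li.tsv"
    write_table(li_matrix_to_long(li_complete), paths["li"])

    log.info("Bayesian lateralisation tests (prior scale %.3g)",
             (prior or PriorSpec()).scale)
    paths["bayes"] = out / "bayes.tsv"
    write_table(bayes_table(li_complete, prior), paths["bayes"])

    log.info("VI permutation family: n_perm=%d", n_perm)
    vi = vi_family_analysis(table, n_perm=n_perm, seed=_stage_seed(seed, "vi"))
    for r in vi:
        if r.missing:
            log.warning("VI test skipped for %s/%s: %s", r.observation.tract,
                        r.observation.metric, r.note)
    paths["vi"] = out / "vi_results.tsv"
    write_table(vi_results_frame(vi), paths["vi"])

    log.info("phenotype embedding and clusterability")
    emb = embed_phenotypes(li_complete, n_neighbors=n_neighbors,
                           min_dist=min_dist, seed=_stage_seed(seed, "embed"))
    coords = emb.coords.reset_index()
    paths["embedding"] = out / "embedding.tsv"
    write_table(coords, paths["embedding"])
    clus = clusterability(li_complete, seed=_stage_seed(seed, "clusterability"))
    paths["clusterability"] = out / "clusterability.json"
    paths["clusterability"].write_text(json.dumps({
        "hopkins": clus.hopkins,
        "silhouettes": {str(k): v for k, v in clus.silhouettes.items()},
        "silhouette_best_k": clus.silhouette_best_k,
        "silhouette_best": clus.silhouette_best,
        "embed_params": emb.embed_params,
    }, indent=2))

    manifest = build_manifest(seed, config=config_digest_src,
                              inputs=[cohort_path] if cohort_path else [])
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
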