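"""Retrieval metrics and the end-to-end benchmark harness.

The benchmark regenerates the study conditions from a seed: a synthetic
corpus is generated and indexed, one query per sheet per motif size (2–10
edges, one wildcard each) is drawn, and every query is run through the
index–filter–verify pipeline. Results are scored against the exhaustive
sliding-window oracle (micro-averaged precision/recall/F1) and the
*filtering precision* — total verified hits over total candidates surviving
both filters — is reported per query size.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .datagen import GenConfig, QUERY_SIZES, gen_matrices, gen_query
from .index import build_indices
from .query import expand_wildcards, naive_match, search_detailed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalCounts:
    """Precision / recall / F-score for a TP/FP/FN tally."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_beta: float
    beta: float = 1.0


def prf(tp: int, fp: int, fn: int, beta: float = 1.0) -> EvalCounts:
    """Precision, recall, and the F_β harmonic mean.

    Empty denominators are defined as 0 by convention (and logged), so a
    workload with no predictions or no relevant items scores zero rather
    than failing.
    """
    if tp + fp == 0:
        logger.debug("prf: no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.debug("prf: no relevant items; recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    b2 = beta * beta
    if precision + recall == 0:
        f = 0.0
    else:
        f = (1 + b2) * precision * recall / (b2 * precision + recall)
    return EvalCounts(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
        f_beta=f, beta=beta,
    )


@dataclass
class BenchmarkReport:
    """Seed-reproducible benchmark results.

    ``per_size`` maps query size to counts; ``timings`` (seconds per stage)
    are excluded from the serialized report by default so the report is
    byte-identical across runs with one seed.
    """

    config: GenConfig
    per_size: dict[int, dict] = field(default_factory=dict)
    n_queries: int = 0
    total_hits: int = 0
    total_filtered: int = 0
    eval_counts: EvalCounts | None = None
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def filtering_precision(self) -> float | None:
        if self.total_filtered == 0:
            return None
        return self.total_hits / self.total_filtered

    @property
    def f1(self) -> float:
        return self.eval_counts.f_beta if self.eval_counts else 0.0

    def to_dict(self, include_timings: bool = False) -> dict:
        d = {
            "config": {
                "n_matrices": self.config.n_matrices,
                "n_rows": list(self.config.n_rows),
                "n_cols": list(self.config.n_cols),
                "jitter": self.config.jitter,
                "distribution": self.config.distribution,
                "seed": self.config.seed,
            },
            "n_queries": self.n_queries,
            "total_hits": self.total_hits,
            "total_filtered": self.total_filtered,
            "filtering_precision": self.filtering_precision,
            "f1": self.f1,
            "tp": self.eval_counts.tp if self.eval_counts else 0,
            "fp": self.eval_counts.fp if self.eval_counts else 0,
            "fn": self.eval_counts.fn if self.eval_counts else 0,
            "per_size": {str(k): v for k, v in sorted(self.per_size.items())},
        }
        if include_timings:
            d["timings"] = self.timings
        return d

    def to_json(self, include_timings: bool = False) -> str:
        return json.dumps(
            self.to_dict(include_timings), indent=2, sort_keys=True
        )

    def to_tsv(self) -> str:
        lines = ["size\tn_queries\thits\tfiltered\tprecision"]
        for size, row in sorted(self.per_size.items()):
            p = row["hits"] / row["filtered"] if row["filtered"] else ""
            lines.append(
                f"{size}\t{row['n_queries']}\t{row['hits']}\t"
                f"{row['filtered']}\t{p}"
            )
        return "\n".join(lines) + "\n"


def run_benchmark(
    cfg: GenConfig,
    sizes: tuple[int, ...] = QUERY_SIZES,
    wildcard: bool = True,
) -> BenchmarkReport:
    """Generate, index, query, and score one full synthetic workload.

    Every generated query is guaranteed at least one true hit (its source
    sheet). Search correctness is scored against :func:`naive_match` over
    the whole corpus; filtering precision is hits / post-filter candidates
    summed over every concrete (wildcard-expanded) query.
    """
    report = BenchmarkReport(config=cfg)
    t0 = time.perf_counter()
    matrices = gen_matrices(cfg)
    t1 = time.perf_counter()
    ix = build_indices(matrices)
    t2 = time.perf_counter()
    report.timings["generate"] = t1 - t0
    report.timings["index"] = t2 - t1

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    tp = fp = fn = 0
    t_search = t_oracle = 0.0
    for m in matrices:
        for size in sizes:
            q = gen_query(m, size, rng, wildcard=wildcard)
            if q is None:
                continue
            row = report.per_size.setdefault(
                size, {"n_queries": 0, "hits": 0, "filtered": 0}
            )
            row["n_queries"] += 1
            report.n_queries += 1

            ts = time.perf_counter()
            hits: set[str] = set()
            for concrete in expand_wildcards(q):
                cs = search_detailed(concrete, ix)
                row["filtered"] += len(cs.C2)
                report.total_filtered += len(cs.C2)
                # hit/filtered totals are per concrete query (wildcards are
                # expanded for every method in the protocol); the union of
                # sub-results is what the wildcard query retrieves.
                row["hits"] += len(cs.hits)
                report.total_hits += len(cs.hits)
                hits |= cs.hits
            t_search += time.perf_counter() - ts

            ts = time.perf_counter()
            truth = {c.sheet_id for c in matrices if naive_match(q.matrix, c)}
            t_oracle += time.perf_counter() - ts
            tp += len(hits & truth)
            fp += len(hits - truth)
            fn += len(truth - hits)

    report.timings["search"] = t_search
    report.timings["oracle"] = t_oracle
    report.eval_counts = prf(tp, fp, fn)
    return report
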