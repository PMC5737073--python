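"""Graded relevance judgments, TREC-style run files, and the metric suite.

Judgments are graded 0 (not relevant), 1 (partially relevant), 2 (relevant).
Exact metrics treat unjudged documents as non-relevant: P@k with and without
partial credit, and NDCG@k with linear gains. For pooled-then-sampled
judgment sets, inferred metrics estimate what the exact metrics would have
been under complete judgment: infAP averages the expected precision at
judged relevant documents (inverse-sampling-rate weighted), and infNDCG
imputes expected gains at unjudged pooled ranks and scales judged per-grade
counts by inverse sampling rates to estimate the ideal DCG. Both reduce
exactly to their counterparts when every judgment is present (rate 1).

File dialects: qrels ``qid 0 docid grade [stratum rate]``; runs
``qid Q0 docid rank score tag``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Qrels",
    "MetricsReport",
    "QrelsError",
    "precision_at_k",
    "ndcg_at_k",
    "average_precision",
    "inf_ap",
    "inf_ndcg",
    "load_judgments",
    "write_judgments",
    "load_run",
    "write_run",
    "evaluate_run",
]

METRIC_NAMES = ("P10_plus_partial", "P10_minus_partial", "NDCG10", "infAP", "infNDCG")


class QrelsError(ValueError):
    pass


@dataclass
class Qrels:
    """Graded judgments plus optional sampling strata for inferred metrics."""

    # strata may also cover docs absent from grades: pool members that were
    # sampled out, which the inferred metrics must distinguish from docs that
    # were never pooled at all
    grades: dict[tuple[str, str], int] = field(default_factory=dict)
    strata: dict[tuple[str, str], tuple[str, float]] = field(default_factory=dict)

    def query_ids(self) -> list[str]:
        return sorted({qid for qid, _ in self.grades})

    def grade(self, query_id: str, doc_id: str) -> int | None:
        return self.grades.get((query_id, doc_id))

    def judged_docs(self, query_id: str) -> dict[str, int]:
        return {d: g for (q, d), g in self.grades.items() if q == query_id}

    def rate(self, query_id: str, doc_id: str) -> float:
        return self.strata.get((query_id, doc_id), ("", 1.0))[1]

    def stratum(self, query_id: str, doc_id: str) -> str | None:
        entry = self.strata.get((query_id, doc_id))
        return entry[0] if entry else None


@dataclass
class MetricsReport:
    per_query: dict[str, dict[str, float]] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Exact metrics


def precision_at_k(
    ranked_docs: list[str],
    qrels: Qrels,
    query_id: str,
    k: int = 10,
    count_partial: bool = True,
) -> float:
    """Fraction of the top k that is relevant; divisor is k, not |retrieved|."""
    threshold = 1 if count_partial else 2
    hits = sum(
        1
        for doc_id in ranked_docs[:k]
        if (qrels.grade(query_id, doc_id) or 0) >= threshold
    )
    return hits / k


def _dcg(gains: list[float], k: int) -> float:
    return sum(g / math.log2(i + 2) for i, g in enumerate(gains[:k]))


def ndcg_at_k(ranked_docs: list[str], qrels: Qrels, query_id: str, k: int = 10) -> float:
    """NDCG with linear gains (gain = grade); unjudged docs gain 0.

    The ideal DCG uses all judged documents for the query sorted by grade.
    """
    gains = [float(qrels.grade(query_id, d) or 0) for d in ranked_docs]
    ideal = sorted(qrels.judged_docs(query_id).values(), reverse=True)
    idcg = _dcg([float(g) for g in ideal], k)
    if idcg == 0:
        return 0.0
    return _dcg(gains, k) / idcg


def average_precision(ranked_docs: list[str], qrels: Qrels, query_id: str) -> float:
    """Binary AP: grades >= 1 count as relevant; denominator is all judged relevant."""
    n_relevant = sum(1 for g in qrels.judged_docs(query_id).values() if g >= 1)
    if n_relevant == 0:
        return 0.0
    hits = 0
    total = 0.0
    for rank, doc_id in enumerate(ranked_docs, start=1):
        if (qrels.grade(query_id, doc_id) or 0) >= 1:
            hits += 1
            total += hits / rank
    return total / n_relevant


# ---------------------------------------------------------------------------
# Inferred metrics


def _expected_precision_at(
    rank: int, ranked_docs: list[str], qrels: Qrels, query_id: str
) -> float:
    """Expected precision at a (1-based) rank holding a judged relevant doc.

    The number of relevant documents above the rank is estimated by
    inverse-sampling-rate weighting of the judged documents above
    (Horvitz-Thompson): each judged relevant document counts 1/rate, unjudged
    documents count zero. This is exactly unbiased under within-stratum
    uniform sampling and gives the exact precision when everything above is
    judged at rate 1.
    """
    if rank == 1:
        return 1.0
    expected_rel_above = 0.0
    for doc_id in ranked_docs[: rank - 1]:
        grade = qrels.grade(query_id, doc_id)
        if grade is not None and grade >= 1:
            expected_rel_above += 1.0 / qrels.rate(query_id, doc_id)
    return (1.0 + expected_rel_above) / rank


def inf_ap(ranked_docs: list[str], qrels: Qrels, query_id: str) -> float:
    """Inferred average precision under sampled judgments.

    The estimate is the ratio of two inverse-sampling-rate (Horvitz-Thompson)
    sums: the expected precision mass at judged relevant retrieved ranks over
    the estimated number of relevant documents. Both sums are exactly
    unbiased, and the leading-order bias of their ratio (numerator and
    denominator share the sampled relevant documents) is removed with an
    analytic plug-in correction, leaving only O(1/R^2) bias. Equals
    :func:`average_precision` exactly when everything retrieved is judged at
    rate 1; judged relevant documents that were not retrieved contribute only
    to the denominator. Clamped to [0, 1].
    """
    judged = qrels.judged_docs(query_id)
    relevant = sorted(d for d, g in judged.items() if g >= 1)
    if not relevant or not ranked_docs:
        return 0.0
    rank_of = {d: i + 1 for i, d in enumerate(ranked_docs)}
    rates = {d: qrels.rate(query_id, d) for d in relevant}
    r_hat = sum(1.0 / rates[d] for d in relevant)
    total = 0.0
    for doc_id in relevant:
        rank = rank_of.get(doc_id)
        if rank is not None:
            total += _expected_precision_at(rank, ranked_docs, qrels, query_id) / rates[doc_id]
    estimate = total / r_hat
    # first-order ratio-bias correction: Cov(T, R_hat) and Var(R_hat) are
    # linear/bilinear in the known Bernoulli inclusions, so both have
    # unbiased plug-in estimates from the sample itself
    var_hat = sum((1 - rates[d]) / rates[d] ** 2 for d in relevant)
    cov_hat = 0.0
    retrieved = [d for d in relevant if d in rank_of]
    for d in retrieved:
        p_d = rates[d]
        rank = rank_of[d]
        cov_hat += (1 - p_d) / (p_d * p_d * rank)
        for e in retrieved:
            if rank_of[e] < rank:
                p_e = rates[e]
                cov_hat += ((1 - p_d) / p_d + (1 - p_e) / p_e) / (p_d * p_e * rank)
    estimate += (cov_hat - estimate * var_hat) / r_hat**2
    return min(1.0, max(0.0, estimate))


def _inferred_ideal_dcg(qrels: Qrels, query_id: str, k: int) -> float:
    """Ideal DCG from per-grade counts scaled by inverse sampling rates.

    Fractional estimated counts occupy rank positions fractionally, so the
    estimate varies smoothly and reduces to the exact ideal DCG at rate 1.
    """
    counts = {1: 0.0, 2: 0.0}
    for (qid, doc_id), grade in qrels.grades.items():
        if qid == query_id and grade in counts:
            counts[grade] += 1.0 / qrels.rate(qid, doc_id)
    idcg = 0.0
    remaining = [(2.0, counts[2]), (1.0, counts[1])]
    position = 0
    while position < k:
        discount = 1.0 / math.log2(position + 2)
        capacity = 1.0
        gain_here = 0.0
        for i, (gain, count) in enumerate(remaining):
            if count <= 0 or capacity <= 0:
                continue
            take = min(capacity, count)
            gain_here += gain * take
            capacity -= take
            remaining[i] = (gain, count - take)
        if gain_here == 0:
            break
        idcg += gain_here * discount
        position += 1
    return idcg


def inf_ndcg(ranked_docs: list[str], qrels: Qrels, query_id: str, k: int = 10) -> float:
    """Inferred NDCG@k under sampled judgments.

    The top-k gain mass is estimated by inverse-sampling-rate weighting of
    the judged ranks (a judged document at rank i contributes
    grade / (rate * log2(i+1)); unjudged ranks contribute nothing but their
    expected mass is carried by the weights), which is exactly unbiased for
    the true DCG under within-stratum uniform sampling. The ideal DCG comes
    from inverse-rate-scaled per-grade counts. Reduces to :func:`ndcg_at_k`
    at full judgment. Clamped to [0, 1]: near-perfect rankings are therefore
    estimated conservatively, since a [0, 1]-bounded estimate cannot sit
    above the truth as often as below it when the truth approaches 1.
    """
    dcg = 0.0
    for i, doc_id in enumerate(ranked_docs[:k]):
        grade = qrels.grade(query_id, doc_id)
        if grade:
            dcg += grade / (qrels.rate(query_id, doc_id) * math.log2(i + 2))
    idcg = _inferred_ideal_dcg(qrels, query_id, k)
    if idcg == 0:
        return 0.0
    return min(1.0, dcg / idcg)


# ---------------------------------------------------------------------------
# I/O


def load_judgments(path: str) -> Qrels:
    """Parse ``qid 0 docid grade [stratum rate]`` lines.

    Grade ``-1`` marks a document that belongs to a sampling stratum but was
    not drawn for judging: it contributes pool membership (needed by the
    inferred metrics) and no grade.
    """
    qrels = Qrels()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) not in (4, 6):
                raise QrelsError(f"{path}:{lineno}: expected 4 or 6 columns, got {len(cols)}")
            qid, _iter, doc_id, grade_str = cols[:4]
            try:
                grade = int(grade_str)
            except ValueError as exc:
                raise QrelsError(f"{path}:{lineno}: non-integer grade {grade_str!r}") from exc
            if grade not in (-1, 0, 1, 2):
                raise QrelsError(f"{path}:{lineno}: grade must be -1/0/1/2, got {grade}")
            if grade == -1 and len(cols) != 6:
                raise QrelsError(f"{path}:{lineno}: grade -1 requires stratum and rate")
            if grade != -1:
                qrels.grades[(qid, doc_id)] = grade
            if len(cols) == 6:
                stratum, rate_str = cols[4], cols[5]
                rate = float(rate_str)
                if not 0 < rate <= 1:
                    raise QrelsError(f"{path}:{lineno}: sampling rate {rate} outside (0, 1]")
                qrels.strata[(qid, doc_id)] = (stratum, rate)
    return qrels


def write_judgments(qrels: Qrels, path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        keys = sorted(set(qrels.grades) | set(qrels.strata))
        for qid, doc_id in keys:
            grade = qrels.grades.get((qid, doc_id), -1)
            entry = qrels.strata.get((qid, doc_id))
            if entry:
                handle.write(f"{qid} 0 {doc_id} {grade} {entry[0]} {entry[1]}\n")
            else:
                handle.write(f"{qid} 0 {doc_id} {grade}\n")


def load_run(path: str) -> dict[str, list[str]]:
    """TREC run file to ``{query_id: ranked doc ids}`` (rank order preserved)."""
    rows: dict[str, list[tuple[int, str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 6:
                raise QrelsError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            qid, _q0, doc_id, rank_str = cols[0], cols[1], cols[2], cols[3]
            rows.setdefault(qid, []).append((int(rank_str), doc_id))
    return {qid: [d for _r, d in sorted(pairs)] for qid, pairs in rows.items()}


def write_run(
    run: dict[str, list[tuple[str, float]]], path: str, tag: str = "biodataseek"
) -> None:
    """Write ``{query_id: [(doc_id, score), ...]}`` in TREC run format."""
    with open(path, "w", encoding="utf-8") as handle:
        for qid in sorted(run):
            for rank, (doc_id, score) in enumerate(run[qid], start=1):
                handle.write(f"{qid} Q0 {doc_id} {rank} {score:.6f} {tag}\n")


# ---------------------------------------------------------------------------
# Reports


def evaluate_run(
    run: dict[str, list[str]],
    qrels: Qrels,
    k: int = 10,
    include_zero_relevant: bool = True,
) -> MetricsReport:
    """Per-query and mean values of the full metric suite.

    Queries judged but absent from the run score zero. Queries with no
    relevant judged documents score zero and are included in the mean unless
    ``include_zero_relevant`` is false.
    """
    report = MetricsReport()
    for query_id in qrels.query_ids():
        judged = qrels.judged_docs(query_id)
        has_relevant = any(g >= 1 for g in judged.values())
        if not has_relevant and not include_zero_relevant:
            continue
        ranked = run.get(query_id, [])
        report.per_query[query_id] = {
            "P10_plus_partial": precision_at_k(ranked, qrels, query_id, k, True),
            "P10_minus_partial": precision_at_k(ranked, qrels, query_id, k, False),
            "NDCG10": ndcg_at_k(ranked, qrels, query_id, k),
            "infAP": inf_ap(ranked, qrels, query_id),
            "infNDCG": inf_ndcg(ranked, qrels, query_id, k),
        }
    n = len(report.per_query)
    for metric in METRIC_NAMES:
        report.mean[metric] = (
            sum(values[metric] for values in report.per_query.values()) / n if n else 0.0
        )
    return report
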