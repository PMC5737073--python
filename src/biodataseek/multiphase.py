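"""Progressively relaxed query sequences with earlier-phase precedence.

To put the most precise results at the top of a ranked list, the strictest
form of the concept-expanded query (every sub-query must match, phrase slop
0, no implicit or descendant expansion) is executed first; subsequent phases
relax one constraint at a time (lower minimum-should-match, wider slop,
descendant/implicit concept expansion, and finally a plain unigram
fallback). Phase result lists are concatenated, with any document already
retrieved by an earlier phase removed from later ones, and truncated to the
requested depth.

Scores are not comparable across phases, so aggregated runs report a
synthetic monotone score (``top_n - rank + 1``) suitable for TREC run files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .index_engine import Index, QueryNode, execute_query
from .ontology_gazetteer import Ontology
from .query_pipeline import (
    ParsedQuery,
    QueryConfig,
    build_concept_expanded_query,
    build_unigram_query,
)

__all__ = [
    "RelaxStep",
    "PhasePlan",
    "AggregatedHit",
    "AggregatedRun",
    "default_schedule",
    "make_phase_plan",
    "execute_phases",
]


@dataclass(frozen=True)
class RelaxStep:
    """One relaxation action: kind in {"msm_concept", "msm_other", "slop",
    "enable_descendants", "enable_implicit", "unigram"}; ``amount`` is the
    decrement for msm steps or the increment for slop steps."""

    kind: str
    amount: int = 1


def default_schedule() -> list[RelaxStep]:
    return [
        RelaxStep("msm_concept", 1),
        RelaxStep("msm_concept", 1),
        RelaxStep("slop", 2),
        RelaxStep("enable_descendants"),
        RelaxStep("enable_implicit"),
        RelaxStep("unigram"),
    ]


@dataclass
class PhasePlan:
    phases: list[tuple[QueryNode, str, dict]] = field(default_factory=list)


@dataclass(frozen=True)
class AggregatedHit:
    doc_id: str
    score: float
    phase_index: int
    rank: int


@dataclass
class AggregatedRun:
    query_id: str
    hits: list[AggregatedHit] = field(default_factory=list)


def _n_concept_subqueries(parsed: ParsedQuery, config: QueryConfig) -> int:
    n = 0
    if config.check_mesh:
        n += len(parsed.mesh_mentions)
    if config.check_genes:
        n += len(parsed.gene_mentions)
    return n


def make_phase_plan(
    parsed: ParsedQuery,
    ontology: Ontology | None,
    config: QueryConfig | None = None,
    schedule: list[RelaxStep] | None = None,
) -> PhasePlan:
    """Build the phase sequence: strictest first, one cumulative step per phase.

    Phase 1 requires every concept sub-query and every other-part clause to
    match, at slop 0, without descendant or implicit expansion. Each schedule
    step then relaxes cumulatively. An empty schedule yields a single phase.
    """
    base = config or QueryConfig()
    n_concepts = _n_concept_subqueries(parsed, base)
    strict = replace(
        base,
        include_descendants=False,
        include_implicit=False,
        msm_concept_part="all",
        msm_other_part="all",
        slop=0,
    )
    plan = PhasePlan()

    def snapshot(cfg: QueryConfig, msm_concept: int) -> dict:
        return {
            "msm_concept": msm_concept,
            "msm_other": cfg.msm_other_part,
            "slop": cfg.slop,
            "descendants": cfg.include_descendants,
            "implicit": cfg.include_implicit,
        }

    current = strict
    msm_concept = max(1, n_concepts)
    plan.phases.append(
        (
            build_concept_expanded_query(parsed, ontology, current),
            "phase1-strict",
            snapshot(current, msm_concept),
        )
    )
    for step_index, step in enumerate(schedule or [], start=2):
        label = f"phase{step_index}-{step.kind}"
        if step.kind == "unigram":
            plan.phases.append(
                (build_unigram_query(parsed), label, {"strategy": "unigram"})
            )
            continue
        if step.kind == "msm_concept":
            msm_concept = max(1, msm_concept - step.amount)
            current = replace(current, msm_concept_part=msm_concept)
        elif step.kind == "msm_other":
            previous = current.msm_other_part
            n_other = len(parsed.other_terms) + len(
                {s for s in parsed.field_tagged_spans}
            )
            base_value = n_other if previous == "all" else int(previous)
            current = replace(current, msm_other_part=max(1, base_value - step.amount))
        elif step.kind == "slop":
            current = replace(current, slop=current.slop + step.amount)
        elif step.kind == "enable_descendants":
            current = replace(current, include_descendants=True)
        elif step.kind == "enable_implicit":
            current = replace(current, include_implicit=True)
        else:
            raise ValueError(f"unknown relaxation step {step.kind!r}")
        plan.phases.append(
            (
                build_concept_expanded_query(parsed, ontology, current),
                label,
                snapshot(current, msm_concept),
            )
        )
    return plan


def execute_phases(
    plan: PhasePlan, index: Index, query_id: str, top_n: int = 1000
) -> AggregatedRun:
    """Run each phase and concatenate with earlier-phase precedence.

    Phases are independent (safe to execute in parallel); a document first
    retrieved in phase i is removed from all later phases; the concatenation
    is truncated to ``top_n`` and ranks reassigned from 1.
    """
    run = AggregatedRun(query_id=query_id)
    seen: set[str] = set()
    for phase_index, (query, _label, _params) in enumerate(plan.phases, start=1):
        if len(run.hits) >= top_n:
            break
        for hit in execute_query(query, index, top_n=top_n):
            if hit.doc_id in seen:
                continue
            seen.add(hit.doc_id)
            rank = len(run.hits) + 1
            run.hits.append(
                AggregatedHit(
                    doc_id=hit.doc_id,
                    score=float(top_n - rank + 1),
                    phase_index=phase_index,
                    rank=rank,
                )
            )
            if len(run.hits) >= top_n:
                break
    return run


def phase_labels(plan: PhasePlan) -> dict[int, str]:
    return {i: label for i, (_q, label, _p) in enumerate(plan.phases, start=1)}
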