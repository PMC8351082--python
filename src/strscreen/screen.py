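"""Cohort screening: candidate reports, trio inheritance, and controls.

A trained (or fixed) decision-tree ensemble is applied to the harmonized
calls of a cohort.  Ensemble-positive sample-locus pairs become candidate
reports annotated with the allelic class and penetrance band implied by the
genotypers' repeat estimates; candidates supported by a single genotyper
and neither outlier tool are flagged for review (genotyper-only calls
without outlier support have a history of failing orthogonal validation).
Parental genotypes, where available, resolve the transmitting parent and
the intergenerational repeat-count change of each expanded allele.

The module also carries the benchmark sensitivity accounting for the
reference cohort of 86 expansion carriers: per-tool, per-locus true-positive
counts ship as package data and sensitivities are recomputed from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import (AllelicClass, LocusDefinition, classify_allele,
                      classify_sample)
from .ensemble import DecisionTree, Hyperparameters, fit_tree
from .harmonize import (GENOTYPER_TOOLS, OUTLIER_TOOLS, GenotypeCall,
                        LabeledMatrix, UnifiedCall)

__all__ = [
    "SampleRecord",
    "CandidateReport",
    "TrioTransmission",
    "fixed_bwa_model",
    "apply_ensemble",
    "trio_inheritance",
    "negative_control_check",
    "allele_length_distribution",
    "load_benchmark_counts",
    "benchmark_sensitivity",
    "candidates_to_frame",
    "read_manifest",
]

VERDICTS = ("full_mutation", "borderline", "intermediate_or_premutation",
            "negative")
ROLES = ("proband", "sibling", "mother", "father")


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member with pedigree role and assay metadata."""

    sample_id: str
    family_id: str
    role: str
    assay: str  # "ES" or "WGS"
    clinical_negative_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.assay not in ("ES", "WGS"):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass(frozen=True)
class TrioTransmission:
    """Parental origin and stability of an inherited expanded allele."""

    origin: str                      # maternal | paternal | unresolved
    parent_allele: Optional[int]
    proband_allele: int
    delta: Optional[int]             # proband - parent repeats
    stability: Optional[str]         # contracted | stable | expanded

    def __post_init__(self) -> None:
        if self.origin not in ("maternal", "paternal", "unresolved"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.delta is not None:
            expected = ("contracted" if self.delta < 0
                        else "stable" if self.delta == 0 else "expanded")
            if self.stability != expected:
                raise ValueError(
                    f"stability {self.stability!r} inconsistent with "
                    f"delta {self.delta}")


@dataclass
class CandidateReport:
    """Screening outcome for one (sample, locus) pair."""

    sample_id: str
    locus_id: str
    verdict: str
    supporting_tools: tuple[str, ...] = ()
    genotypes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    allelic_class: Optional[AllelicClass] = None
    zygosity: Optional[str] = None
    review_recommended: bool = False
    transmission: Optional[TrioTransmission] = None
    evidence: tuple[UnifiedCall, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict != "negative" and not self.supporting_tools:
            raise ValueError("non-negative verdict without supporting tools")


def fixed_bwa_model() -> DecisionTree:
    """The published screening rule for BWA-aligned data.

    The selected tool trio (STRetch, EH_v3, exSTRa) acts as an any-positive
    consensus: a sample-locus pair is expanded when at least one of the
    three flags it.  The rule is materialized as a proper CART by fitting
    the tree on the exhaustive 8-row truth table of that rule, so screening
    works without retraining while node statistics stay well defined.
    """
    tools = ("stretch", "eh_v3", "exstra")
    rows = [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    labels = [int(any(r)) for r in rows]
    tree = fit_tree((np.array(rows), np.array(labels)),
                    Hyperparameters(max_depth=3), tools)
    tree.metadata = {"rule": "any-positive consensus", "aligner": "bwa"}
    return tree


def _best_genotype_class(genotypes: Mapping[str, Sequence[int]],
                         locus: LocusDefinition, mode: str,
                         ) -> tuple[Optional[AllelicClass], Optional[str]]:
    """Highest-ranked allelic class across the genotypers' estimates."""
    best: Optional[AllelicClass] = None
    zygosity = None
    for alleles in genotypes.values():
        cls = classify_sample(locus, tuple(alleles), mode)
        top = cls.max_class
        if best is None or (top.rank, top.repeat_count) > (best.rank,
                                                           best.repeat_count):
            best, zygosity = top, cls.zygosity
    return best, zygosity


def apply_ensemble(model: DecisionTree,
                   calls: Iterable[UnifiedCall],
                   catalog: Mapping[str, LocusDefinition],
                   genotype_calls: Iterable[GenotypeCall] = (),
                   mode: str = "default") -> list[CandidateReport]:
    """Screen harmonized calls with a decision-tree ensemble.

    Every (sample, locus) pair whose flags cover the model's tools is
    evaluated; pairs with a missing model-tool flag are reported with
    verdict ``negative`` and ``review_recommended`` set (not evaluable, not
    silently dropped).  Ensemble-positive pairs become candidates whose
    verdict reflects the best genotyper estimate: ``full_mutation`` (with
    penetrance band), ``borderline``, or ``intermediate_or_premutation``
    when only sub-threshold estimates support an outlier-driven flag.

    Raises
    ------
    ValueError
        If the model references a tool that appears nowhere in *calls*.
    """
    calls = list(calls)
    seen_tools = {c.tool_id for c in calls}
    missing_tools = [t for t in model.feature_names if t not in seen_tools]
    if missing_tools:
        raise ValueError(f"model tools absent from calls: {missing_tools}")
    genotypes: dict[tuple[str, str], dict[str, tuple[int, ...]]] = {}
    for g in genotype_calls:
        if not g.missing:
            genotypes.setdefault((g.sample_id, g.locus_id), {})[
                g.tool_id] = g.alleles
    grouped: dict[tuple[str, str], dict[str, UnifiedCall]] = {}
    for call in calls:
        grouped.setdefault((call.sample_id, call.locus_id), {})[
            call.tool_id] = call
    reports = []
    for (sample_id, locus_id), by_tool in sorted(grouped.items()):
        if locus_id not in catalog:
            raise ValueError(f"unknown locus {locus_id!r}")
        locus = catalog[locus_id]
        flags = {t: by_tool[t].flag for t in model.feature_names
                 if t in by_tool}
        if len(flags) < len(model.feature_names) or None in flags.values():
            reports.append(CandidateReport(
                sample_id, locus_id, "negative", review_recommended=True,
                evidence=tuple(by_tool.values())))
            continue
        row = [[flags[t] for t in model.feature_names]]
        positive = bool(model.predict(row)[0])
        supporting = tuple(sorted(
            t for t, c in by_tool.items() if c.flag == 1))
        if not positive:
            reports.append(CandidateReport(
                sample_id, locus_id, "negative", supporting,
                evidence=tuple(by_tool.values())))
            continue
        geno = genotypes.get((sample_id, locus_id), {})
        best, zygosity = _best_genotype_class(geno, locus, mode)
        if best is None or best.label == "full_mutation":
            verdict = "full_mutation"
        elif best.label == "borderline":
            verdict = "borderline"
        elif best.label in ("intermediate", "premutation"):
            verdict = "intermediate_or_premutation"
        else:
            verdict = "full_mutation"  # outlier-driven, genotypers undersized
        genotyper_support = [t for t in supporting if t in GENOTYPER_TOOLS]
        outlier_support = [t for t in supporting if t in OUTLIER_TOOLS]
        review = len(genotyper_support) == 1 and not outlier_support
        reports.append(CandidateReport(
            sample_id, locus_id, verdict, supporting, dict(geno), best,
            zygosity, review, evidence=tuple(by_tool.values())))
    return reports


def trio_inheritance(family_calls: Iterable[GenotypeCall],
                     locus: LocusDefinition,
                     roles: Mapping[str, str],
                     proband_id: Optional[str] = None,
                     mode: str = "default") -> TrioTransmission:
    """Resolve the parental origin of a proband's expanded allele.

    ``roles`` maps sample IDs to pedigree roles.  The transmitting parent
    is the one carrying the allele closest in repeat count to the proband's
    expanded allele, matching by allelic class first and falling back to
    any expanded (non-normal) parental allele, since transmitted expansions
    can cross a class boundary.  When both parents qualify at equal
    distance, or neither does, the origin is ``unresolved`` (which covers
    apparent de-novo expansions).  Missing parental calls degrade to
    ``unresolved``, never to an error.
    """
    by_role: dict[str, GenotypeCall] = {}
    for call in family_calls:
        if call.locus_id != locus.locus_id or call.missing:
            continue
        role = roles.get(call.sample_id)
        if proband_id is not None and call.sample_id == proband_id:
            role = "proband"
        if role in ("proband", "mother", "father"):
            by_role[role] = call
    if "proband" not in by_role:
        raise ValueError("no genotyped proband call at the locus")
    proband = by_role["proband"]
    expanded = max(proband.alleles)
    target = classify_allele(locus, expanded, mode)
    def _matches(same_class: bool) -> list[tuple[int, str, int]]:
        found = []
        for role, origin in (("mother", "maternal"), ("father", "paternal")):
            call = by_role.get(role)
            if call is None:
                continue
            eligible = [
                a for a in call.alleles
                if (classify_allele(locus, a, mode).label == target.label
                    if same_class
                    else classify_allele(locus, a, mode).rank > 0)]
            if eligible:
                allele = min(eligible, key=lambda a: abs(expanded - a))
                found.append((abs(expanded - allele), origin, allele))
        return found

    candidates = _matches(same_class=True) or (
        _matches(same_class=False) if target.rank > 0 else [])
    if not candidates:
        return TrioTransmission("unresolved", None, expanded, None, None)
    candidates.sort()
    if len(candidates) == 2 and candidates[0][0] == candidates[1][0]:
        return TrioTransmission("unresolved", None, expanded, None, None)
    _, origin, allele = candidates[0]
    delta = expanded - allele
    stability = ("contracted" if delta < 0
                 else "stable" if delta == 0 else "expanded")
    return TrioTransmission(origin, allele, expanded, delta, stability)


def negative_control_check(candidates: Iterable[CandidateReport],
                           samples: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tally candidates at loci with a prior negative clinical test.

    Returns a per-locus false-positive count restricted to (sample, locus)
    pairs covered by a clinical negative; candidates at untested loci are
    out of scope.  Concordant data yield an empty frame.
    """
    negatives = {(s.sample_id, locus)
                 for s in samples for locus in s.clinical_negative_loci}
    counts: dict[str, int] = {}
    for cand in candidates:
        if (cand.verdict != "negative"
                and (cand.sample_id, cand.locus_id) in negatives):
            counts[cand.locus_id] = counts.get(cand.locus_id, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["locus", "false_positives"])


def allele_length_distribution(calls: Iterable[GenotypeCall],
                               locus_id: str, tool_id: str) -> pd.DataFrame:
    """Repeat-length frequency table for one locus and tool.

    Counts every called allele; the returned frame is sorted by descending
    count (then ascending length), so the head gives the most common normal
    alleles for comparison with published population frequencies.
    """
    counts: dict[int, int] = {}
    for call in calls:
        if call.locus_id != locus_id or call.tool_id != tool_id:
            continue
        for allele in call.alleles:
            counts[allele] = counts.get(allele, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["repeat_count", "n_alleles"])


def candidates_to_frame(candidates: Iterable[CandidateReport]) -> pd.DataFrame:
    """Flatten candidate reports for TSV export."""
    rows = []
    for c in candidates:
        cls = c.allelic_class
        rows.append({
            "sample": c.sample_id,
            "locus": c.locus_id,
            "verdict": c.verdict,
            "supporting_tools": ",".join(c.supporting_tools),
            "allelic_class": cls.label if cls else "",
            "penetrance": (cls.penetrance or "") if cls else "",
            "zygosity": c.zygosity or "",
            "review_recommended": c.review_recommended,
            "origin": c.transmission.origin if c.transmission else "",
            "delta": (c.transmission.delta
                      if c.transmission and c.transmission.delta is not None
                      else ""),
        })
    return pd.DataFrame(rows)


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a sample manifest TSV.

    Columns: ``sample``, ``family``, ``role``, ``assay``, and an optional
    ``clinical_negative_loci`` column of comma-separated locus IDs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        neg = getattr(row, "clinical_negative_loci", "")
        loci = tuple(x for x in str(neg).split(",") if x)
        records.append(SampleRecord(str(row.sample), str(row.family),
                                    str(row.role), str(row.assay), loci))
    seen = set()
    for rec in records:
        key = (rec.family_id, rec.sample_id)
        if key in seen:
            raise ValueError(f"duplicate sample {key} in manifest")
        seen.add(key)
    return records


# ---------------------------------------------------------------------------
# Benchmark sensitivity accounting
# ---------------------------------------------------------------------------

def load_benchmark_counts() -> dict:
    """Packaged per-tool, per-locus benchmark detection counts."""
    text = (resources.files("strscreen.data")
            / "benchmark_counts.yaml").read_text()
    return yaml.safe_load(text)


def benchmark_sensitivity(aligner: str, tool_id: str,
                          counts: Optional[dict] = None) -> float:
    """Recompute a tool's benchmark sensitivity from its per-locus counts.

    Sensitivity = (sum of per-locus true positives) / (total expansion
    carriers in the benchmark cohort).
    """
    counts = counts or load_benchmark_counts()
    row = counts["aligners"][aligner][tool_id]
    n_true = sum(counts["truth"])
    return sum(row["tp"]) / n_true
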