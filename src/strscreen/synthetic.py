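"""Synthetic labeled STR cohorts and tool-dialect fixture files.

Real benchmark and patient cohorts for repeat-expansion screening are
access-restricted, so this module generates cohorts with the statistical
structure the pipeline assumes: each affected sample carries exactly one
full-mutation expansion at a known disease locus, every sample additionally
carries normal alleles at all other catalog loci, and each analysis tool
observes the truth through its own error model.

Tool error models are phenomenological, not mechanistic: a genotyper has a
per-locus detection sensitivity (missed expansions are *under-sized* into
the sub-threshold range, mirroring the behaviour of read-based genotypers
on GC-rich loci), a false-positive rate, and a missingness rate; an outlier
tool emits a p-value whose significant component fires with exactly the
configured sensitivity (on expansions) or false-positive rate (elsewhere).
Significant p-values are drawn far below the decision threshold so that
downstream multiple-testing adjustment preserves the configured flag
outcome; non-significant p-values are drawn from the non-significant part
of the uniform null.

All randomness flows from one seed through ``numpy.random.default_rng``;
identical configuration and seed reproduce byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .catalog import LocusDefinition, catalog_by_id, default_catalog
from .harmonize import (GENOTYPER_TOOLS, OUTLIER_TOOLS, GenotypeCall,
                        LABEL_FM, LABEL_NON_FM, OutlierResult)

__all__ = [
    "ToolProfile",
    "CohortConfig",
    "SimulatedCohort",
    "SimulatedFamily",
    "ega_like_fm_counts",
    "ega_like_config",
    "default_tool_profiles",
    "simulate_cohort",
    "simulate_trios",
    "write_fixtures",
    "write_truth_labels",
]

#: Modal normal-allele repeat counts used by the default length
#: distributions (literature modal values for European-ancestry cohorts).
MODAL_NORMAL = {
    "AR": 22, "ATN1": 15, "ATXN1": 29, "ATXN2": 22, "ATXN3": 22,
    "ATXN8": 25, "C9orf72": 5, "DMPK": 12, "FMR1": 30, "FMR2": 20,
    "FXN": 9, "HTT": 17,
}

#: Per-locus true-expansion counts of the reference benchmark cohort
#: (86 carriers, one characterized expansion each).
EGA_FM_COUNTS = {
    "AR": 1, "ATN1": 2, "ATXN1": 3, "ATXN3": 1, "C9orf72": 3,
    "DMPK": 17, "FMR1": 18, "FMR2": 3, "FXN": 25, "HTT": 13,
}


def _per_locus(value: Union[float, Mapping[str, float]], locus_id: str,
               ) -> float:
    if isinstance(value, Mapping):
        return float(value.get(locus_id, value.get("default", 0.0)))
    return float(value)


@dataclass(frozen=True)
class ToolProfile:
    """Error model of one STR analysis tool.

    ``sensitivity`` and ``fp_rate`` may be scalars or per-locus mappings
    (with an optional ``"default"`` key).  ``undersize_max`` bounds the
    downward sizing error applied to *detected* expansions (genotypers
    only); missed expansions are re-drawn uniformly from the sub-threshold
    range.  ``p_alt_max`` is the upper bound of significant outlier
    p-values.
    """

    tool_id: str
    sensitivity: Union[float, Mapping[str, float]] = 1.0
    fp_rate: Union[float, Mapping[str, float]] = 0.0
    missingness: float = 0.0
    undersize_max: int = 0
    p_alt_max: float = 1e-6

    def __post_init__(self) -> None:
        if self.tool_id not in GENOTYPER_TOOLS + OUTLIER_TOOLS:
            raise ValueError(f"unknown tool {self.tool_id!r}")
        for name in ("missingness", "p_alt_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("sensitivity", "fp_rate"):
            v = getattr(self, name)
            values = v.values() if isinstance(v, Mapping) else (v,)
            if any(not 0.0 <= float(x) <= 1.0 for x in values):
                raise ValueError(f"{name} outside [0, 1]")
        if self.undersize_max and self.tool_id in OUTLIER_TOOLS:
            raise ValueError("undersizing applies only to genotypers")

    @property
    def is_genotyper(self) -> bool:
        return self.tool_id in GENOTYPER_TOOLS


@dataclass(frozen=True)
class CohortConfig:
    """Composition of a simulated cohort.

    ``fm_counts`` gives the number of samples carrying a true full-mutation
    per locus (one expansion per sample); ``premutation_counts`` adds
    carriers of sub-threshold expanded alleles (drawn from the locus's
    premutation range).  ``expansion_excess`` bounds how far above the
    full-mutation minimum true expansions are drawn.
    """

    loci: tuple[str, ...]
    fm_counts: Mapping[str, int] = field(default_factory=dict)
    premutation_counts: Mapping[str, int] = field(default_factory=dict)
    n_unaffected: int = 0
    modal_normal: Mapping[str, int] = field(
        default_factory=lambda: dict(MODAL_NORMAL))
    expansion_excess: int = 400
    trio: bool = False
    transmission_delta_range: tuple[int, int] = (1, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        for counts in (self.fm_counts, self.premutation_counts):
            for locus, n in counts.items():
                if locus not in self.loci:
                    raise ValueError(f"count for locus {locus!r} not in loci")
                if n < 0:
                    raise ValueError("counts must be >= 0")
        if self.n_unaffected < 0:
            raise ValueError("n_unaffected must be >= 0")


@dataclass
class SimulatedCohort:
    """Ground truth plus per-tool observations of a simulated cohort."""

    truth: dict[tuple[str, str], str]
    true_genotypes: dict[tuple[str, str], tuple[int, ...]]
    genotype_calls: list[GenotypeCall]
    outlier_results: list[OutlierResult]
    samples: list[str]


@dataclass
class SimulatedFamily:
    """A simulated trio with the transmission ground truth."""

    family_id: str
    locus_id: str
    calls: list[GenotypeCall]          # proband, mother, father
    roles: dict[str, str]
    true_origin: str                   # maternal | paternal
    true_delta: int


def ega_like_fm_counts() -> dict[str, int]:
    return dict(EGA_FM_COUNTS)


def ega_like_config(seed: int = 0, n_unaffected: int = 32) -> CohortConfig:
    """Benchmark-like cohort: 86 expansion carriers across 10 loci plus
    unaffected samples (118 samples total at the default 32)."""
    return CohortConfig(loci=tuple(EGA_FM_COUNTS), fm_counts=EGA_FM_COUNTS,
                        n_unaffected=n_unaffected, seed=seed)


#: Per-tool benchmark-derived false-positive rates (false positives over
#: roughly 1100 non-expanded sample-locus pairs).
DEFAULT_FP_RATE = {
    "eh_v2": 0.005, "eh_v3": 0.005, "gangstr": 0.007, "tredparse": 0.009,
    "stretch": 0.024, "exstra": 0.032,
}

#: Default-parameter sensitivities of the weak tier (benchmark totals /86).
DEFAULT_WEAK_SENSITIVITY = {
    "eh_v2": 0.74, "gangstr": 0.38, "tredparse": 0.72,
}


def default_tool_profiles(strong: Sequence[str] = ("eh_v3", "stretch",
                                                   "exstra"),
                          weak: Sequence[str] = ("eh_v2", "gangstr",
                                                 "tredparse"),
                          strong_sensitivity: float = 1.0,
                          weak_sensitivity: Union[float, Mapping[str, float],
                                                  None] = None,
                          fp_rate: Union[float, Mapping[str, float],
                                         None] = None,
                          missingness: float = 0.002,
                          ) -> list[ToolProfile]:
    """Profiles with a strong and a weak tool tier.

    The defaults emulate the benchmark picture after parameter
    optimisation: the strong trio detects essentially every expansion
    (sensitised thresholds and control-augmented outlier analysis), the
    weak tier keeps its default-parameter sensitivities, and per-tool
    false-positive rates reflect the benchmark false-positive tallies.
    Because false positives are independent across tools, a conjunctive
    ensemble can out-precise any single tool at equal recall.
    """
    fp = dict(DEFAULT_FP_RATE) if fp_rate is None else fp_rate
    weak_sens = (dict(DEFAULT_WEAK_SENSITIVITY) if weak_sensitivity is None
                 else weak_sensitivity)

    def _get(table, tool, fallback):
        if isinstance(table, Mapping):
            return table.get(tool, fallback)
        return table

    profiles = []
    for tool in strong:
        profiles.append(ToolProfile(tool, strong_sensitivity,
                                    _get(fp, tool, 0.01), missingness))
    for tool in weak:
        profiles.append(ToolProfile(tool, _get(weak_sens, tool, 0.6),
                                    _get(fp, tool, 0.01), missingness))
    return profiles


# ---------------------------------------------------------------------------
# Genotype and observation draws
# ---------------------------------------------------------------------------

def _draw_normal_allele(rng: np.random.Generator, locus: LocusDefinition,
                        modal: int) -> int:
    """Truncated two-sided geometric around the modal normal length."""
    offset = int(rng.geometric(0.5)) - 1
    sign = -1 if rng.random() < 0.5 else 1
    return int(np.clip(modal + sign * offset, 1, locus.normal_max))


def _draw_undersized(rng: np.random.Generator, locus: LocusDefinition,
                     modal: int) -> int:
    """A missed expansion, re-sized below the full-mutation minimum."""
    lo = locus.normal_max + 1
    hi = locus.fm_threshold - 1
    if lo > hi:
        return _draw_normal_allele(rng, locus, modal)
    return int(rng.integers(lo, hi + 1))


def simulate_cohort(config: CohortConfig,
                    profiles: Sequence[ToolProfile],
                    catalog: Iterable[LocusDefinition] | None = None,
                    ) -> SimulatedCohort:
    """Draw true genotypes and per-tool observations for a cohort.

    Sample layout is deterministic: expansion carriers first (ordered by
    the locus order of ``config.loci``), then premutation carriers, then
    unaffected samples.  X-linked loci are hemizygous in samples drawn as
    male.  Truth labels mark each sample's expansion locus ``full_mutation``
    and every other (sample, locus) pair ``non_full_mutation``.
    """
    by_id = catalog_by_id(catalog if catalog is not None else
                          default_catalog())
    missing_loci = [l for l in config.loci if l not in by_id]
    if missing_loci:
        raise ValueError(f"loci absent from catalog: {missing_loci}")
    rng = np.random.default_rng(config.seed)

    plan: list[tuple[str, Optional[str], str]] = []  # (sample, locus, kind)
    i = 0
    for locus_id in config.loci:
        for _ in range(int(config.fm_counts.get(locus_id, 0))):
            plan.append((f"S{i:04d}", locus_id, "fm"))
            i += 1
    for locus_id in config.loci:
        for _ in range(int(config.premutation_counts.get(locus_id, 0))):
            plan.append((f"S{i:04d}", locus_id, "pm"))
            i += 1
    for _ in range(config.n_unaffected):
        plan.append((f"S{i:04d}", None, "none"))
        i += 1

    truth: dict[tuple[str, str], str] = {}
    true_genotypes: dict[tuple[str, str], tuple[int, ...]] = {}
    for sample_id, affected_locus, kind in plan:
        is_male = bool(rng.random() < 0.5)
        for locus_id in config.loci:
            locus = by_id[locus_id]
            modal = int(config.modal_normal.get(locus_id, 20))
            hemi = is_male and locus.inheritance == "X_linked"
            n_alleles = 1 if hemi else 2
            alleles = [_draw_normal_allele(rng, locus, modal)
                       for _ in range(n_alleles)]
            if locus_id == affected_locus:
                if kind == "fm":
                    alleles[-1] = int(rng.integers(
                        locus.fm_threshold,
                        locus.fm_threshold + config.expansion_excess + 1))
                else:  # premutation carrier
                    rng_lo, rng_hi = (locus.premutation_range
                                      or (locus.normal_max + 1,
                                          locus.fm_threshold - 1))
                    alleles[-1] = int(rng.integers(rng_lo, rng_hi + 1))
            label = LABEL_FM if (locus_id == affected_locus and kind == "fm"
                                 ) else LABEL_NON_FM
            truth[(sample_id, locus_id)] = label
            true_genotypes[(sample_id, locus_id)] = tuple(alleles)

    genotype_calls: list[GenotypeCall] = []
    outlier_results: list[OutlierResult] = []
    for profile in profiles:
        for (sample_id, locus_id), alleles in true_genotypes.items():
            locus = by_id[locus_id]
            sens = _per_locus(profile.sensitivity, locus_id)
            fp = _per_locus(profile.fp_rate, locus_id)
            is_fm = truth[(sample_id, locus_id)] == LABEL_FM
            if profile.is_genotyper:
                call = _observe_genotype(rng, profile, locus, sample_id,
                                         alleles, is_fm, sens, fp,
                                         int(config.modal_normal.get(
                                             locus_id, 20)))
                genotype_calls.append(call)
            else:
                res = _observe_outlier(rng, profile, locus, sample_id,
                                       is_fm, sens, fp)
                outlier_results.append(res)
    return SimulatedCohort(truth, true_genotypes, genotype_calls,
                           outlier_results, [p[0] for p in plan])


def _observe_genotype(rng, profile, locus, sample_id, alleles, is_fm,
                      sens, fp, modal) -> GenotypeCall:
    if rng.random() < profile.missingness:
        return GenotypeCall(sample_id, locus.locus_id, profile.tool_id)
    observed = []
    for allele in alleles:
        if allele >= locus.fm_threshold:
            if rng.random() < sens:
                est = allele
                if profile.undersize_max:
                    est -= int(rng.integers(0, profile.undersize_max + 1))
                observed.append(max(locus.fm_threshold, est))
            else:
                observed.append(_draw_undersized(rng, locus, modal))
        else:
            observed.append(allele)
    if not is_fm and rng.random() < fp:
        observed[-1] = int(rng.integers(locus.fm_threshold,
                                        locus.fm_threshold + 101))
    a1 = observed[0]
    a2 = observed[1] if len(observed) == 2 else None
    return GenotypeCall(sample_id, locus.locus_id, profile.tool_id, a1, a2)


def _observe_outlier(rng, profile, locus, sample_id, is_fm, sens, fp,
                     ) -> OutlierResult:
    if rng.random() < profile.missingness:
        return OutlierResult(sample_id, locus.locus_id, profile.tool_id)
    significant = rng.random() < (sens if is_fm else fp)
    if significant:
        p = float(rng.uniform(0.0, profile.p_alt_max))
    else:
        # the non-significant part of the uniform null, so multiple-testing
        # adjustment cannot flip the configured flag outcome
        p = float(rng.uniform(0.05, 1.0))
    if profile.tool_id == "stretch":
        return OutlierResult(sample_id, locus.locus_id, profile.tool_id,
                             p_raw=None, p_adj=p)
    return OutlierResult(sample_id, locus.locus_id, profile.tool_id,
                         p_raw=p, p_adj=None)


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------

def simulate_trios(config: CohortConfig,
                   catalog: Iterable[LocusDefinition] | None = None,
                   tool_id: str = "eh_v3") -> list[SimulatedFamily]:
    """Simulate proband-mother-father trios at each expansion locus.

    Each family's proband carries one expanded allele inherited from a
    randomly chosen parent; the transmitted allele grew by a delta drawn
    from ``transmission_delta_range`` (clipped so the parental allele stays
    in the full-mutation range, keeping the origin resolvable).  The
    proband's other allele follows Mendelian inheritance from the other
    parent.
    """
    by_id = catalog_by_id(catalog if catalog is not None else
                          default_catalog())
    rng = np.random.default_rng([config.seed, 1])
    d_lo, d_hi = config.transmission_delta_range
    families = []
    fam_i = 0
    for locus_id in config.loci:
        locus = by_id[locus_id]
        modal = int(config.modal_normal.get(locus_id, 20))
        for _ in range(int(config.fm_counts.get(locus_id, 0))):
            fam = f"F{fam_i:04d}"
            fam_i += 1
            delta = int(rng.integers(d_lo, d_hi + 1)) if d_hi >= d_lo else 0
            proband_exp = int(rng.integers(
                locus.fm_threshold + max(delta, 0),
                locus.fm_threshold + max(delta, 0)
                + config.expansion_excess + 1))
            parent_exp = proband_exp - delta
            origin = "maternal" if rng.random() < 0.5 else "paternal"
            carrier, other = (("mother", "father") if origin == "maternal"
                              else ("father", "mother"))
            other_alleles = tuple(
                _draw_normal_allele(rng, locus, modal) for _ in range(2))
            proband_normal = other_alleles[int(rng.integers(0, 2))]
            genos = {
                "proband": (proband_normal, proband_exp),
                carrier: (_draw_normal_allele(rng, locus, modal), parent_exp),
                other: other_alleles,
            }
            ids = {role: f"{fam}-{role}" for role in
                   ("proband", "mother", "father")}
            calls = [GenotypeCall(ids[role], locus_id, tool_id,
                                  genos[role][0], genos[role][1])
                     for role in ("proband", "mother", "father")]
            roles = {ids[role]: role for role in ids}
            families.append(SimulatedFamily(fam, locus_id, calls, roles,
                                            origin, delta))
    return families


# ---------------------------------------------------------------------------
# Fixture writers (round-trip with strscreen.harmonize parsers)
# ---------------------------------------------------------------------------

def _write_eh_json(calls: Sequence[GenotypeCall], path: Path) -> None:
    sample_id = calls[0].sample_id
    locus_results = {}
    for call in calls:
        var: dict = {"VariantId": call.locus_id}
        if not call.missing:
            geno = "/".join(str(a) for a in call.alleles)
            var["Genotype"] = geno
            var["GenotypeConfidenceInterval"] = "/".join(
                f"{a}-{a}" for a in call.alleles)
        locus_results[call.locus_id] = {
            "LocusId": call.locus_id,
            "Variants": {call.locus_id: var},
        }
    doc = {"SampleId": sample_id, "LocusResults": locus_results}
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _write_vcf(calls: Sequence[GenotypeCall], path: Path,
               by_id: Mapping[str, LocusDefinition], dialect: str) -> None:
    sample_id = calls[0].sample_id
    use_repcn = dialect == "gangstr"
    lines = ["##fileformat=VCFv4.2"]
    contigs = []
    for locus_id in sorted({c.locus_id for c in calls}):
        chrom = by_id[locus_id].chrom
        if chrom not in contigs:
            contigs.append(chrom)
    lines += [f"##contig=<ID={c}>" for c in sorted(contigs)]
    if use_repcn:
        lines.append('##FORMAT=<ID=REPCN,Number=.,Type=Integer,'
                     'Description="Repeat copy numbers per allele">')
    else:
        lines.append('##FORMAT=<ID=GB,Number=1,Type=String,'
                     'Description="Genotype in repeat units">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample_id)
    for call in sorted(calls, key=lambda c: (by_id[c.locus_id].chrom,
                                             by_id[c.locus_id].start)):
        locus = by_id[call.locus_id]
        if call.missing:
            value = "." if use_repcn else "./."
        elif use_repcn:
            value = ",".join(str(a) for a in call.alleles)
        else:
            value = "/".join(str(a) for a in call.alleles)
        fmt = "REPCN" if use_repcn else "GB"
        lines.append("\t".join([
            locus.chrom, str(locus.start), call.locus_id, "N", ".", ".",
            "PASS", ".", fmt, value]))
    path.write_text("\n".join(lines) + "\n")


def _write_outlier_tsv(results: Sequence[OutlierResult], path: Path,
                       dialect: str) -> None:
    col = "p_adj" if dialect == "stretch" else "p"
    lines = ["\t".join(["sample", "locus", col])]
    for res in results:
        p = res.p_adj if dialect == "stretch" else res.p_raw
        lines.append("\t".join([res.sample_id, res.locus_id,
                                "" if p is None else repr(p)]))
    path.write_text("\n".join(lines) + "\n")


def write_fixtures(cohort: SimulatedCohort, out_dir: str | Path,
                   catalog: Iterable[LocusDefinition] | None = None,
                   ) -> list[Path]:
    """Write one file per sample per tool in that tool's dialect.

    EH-style tools produce JSON, the VCF genotypers single-sample VCFs, and
    the outlier tools TSV tables; all are parseable by the corresponding
    :mod:`strscreen.harmonize` parser with round-trip identity of the call
    set (p-values round-trip via ``repr`` to full precision).
    """
    by_id = catalog_by_id(catalog if catalog is not None else
                          default_catalog())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grouped: dict[tuple[str, str], list] = {}
    for call in cohort.genotype_calls:
        grouped.setdefault((call.sample_id, call.tool_id), []).append(call)
    for res in cohort.outlier_results:
        grouped.setdefault((res.sample_id, res.tool_id), []).append(res)
    paths = []
    for (sample_id, tool_id), records in sorted(grouped.items()):
        if tool_id in ("eh_v2", "eh_v3"):
            path = out_dir / f"{sample_id}.{tool_id}.json"
            _write_eh_json(records, path)
        elif tool_id in GENOTYPER_TOOLS:
            path = out_dir / f"{sample_id}.{tool_id}.vcf"
            _write_vcf(records, path, by_id, tool_id)
        else:
            path = out_dir / f"{sample_id}.{tool_id}.tsv"
            _write_outlier_tsv(records, path, tool_id)
        paths.append(path)
    return paths


def write_truth_labels(cohort: SimulatedCohort, path: str | Path) -> None:
    lines = ["sample\tlocus\tlabel"]
    for (sample_id, locus_id), label in sorted(cohort.truth.items()):
        lines.append(f"{sample_id}\t{locus_id}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")
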