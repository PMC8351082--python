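"""Harmonization of heterogeneous STR-tool outputs into unified binary calls.

Two families of tools feed the screen: *genotypers* report per-allele repeat
counts (ExpansionHunter-style JSON; GangSTR / TREDPARSE / spanning-caller
VCFs), while *outlier tests* report per-locus p-values against a control
distribution (STRetch-style TSV with adjusted p-values; exSTRa-style tables
of raw p-values).  Each tool's output is reduced to the minimal field
contract listed below, binarized against the locus catalog, and assembled
into a labeled sample-by-locus-by-tool call matrix.

Dialect field contracts
-----------------------
``eh_v2`` / ``eh_v3``
    JSON with a top-level ``SampleId`` and ``LocusResults[locus]["Variants"]
    [locus]["Genotype"]`` holding ``"a1/a2"`` (or ``"a1"`` when hemizygous),
    with an optional ``GenotypeConfidenceInterval`` ``"lo-hi/lo-hi"``.
``gangstr``
    Single-sample VCF, record ID = locus, FORMAT field ``REPCN`` holding
    comma-separated per-allele repeat counts.
``tredparse`` / ``lobstr`` / ``hipstr`` / ``repeatseq``
    Single-sample VCF, record ID = locus, FORMAT field ``GB`` holding
    ``a1/a2`` repeat counts (``.`` for missing).
``stretch``
    TSV with columns ``sample``, ``locus``, ``p_adj`` (adjusted p-values,
    as the tool reports them).
``exstra``
    TSV with columns ``sample``, ``locus``, ``p`` (raw p-values; adjustment
    happens downstream via :func:`adjust_pvalues`).

A call is binarized to 1 when at least one allele classifies full-mutation
(genotypers, under the selected threshold mode) or when the adjusted p-value
is strictly below alpha (outlier tools, default 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam
from statsmodels.stats.multitest import multipletests

from .catalog import LocusDefinition, classify_sample

__all__ = [
    "GENOTYPER_TOOLS",
    "OUTLIER_TOOLS",
    "GenotypeCall",
    "OutlierResult",
    "UnifiedCall",
    "LabeledMatrix",
    "HarmonizeError",
    "parse_genotyper_output",
    "parse_outlier_output",
    "adjust_pvalues",
    "adjust_outlier_results",
    "binarize",
    "binarize_all",
    "build_labeled_matrix",
]

GENOTYPER_TOOLS = ("eh_v2", "eh_v3", "gangstr", "tredparse",
                   "lobstr", "hipstr", "repeatseq")
OUTLIER_TOOLS = ("stretch", "exstra")

LABEL_FM = "full_mutation"
LABEL_NON_FM = "non_full_mutation"


class HarmonizeError(ValueError):
    """Raised for malformed tool outputs or inconsistent matrix inputs."""


@dataclass(frozen=True)
class GenotypeCall:
    """A genotyper's repeat-count call for one sample at one locus."""

    sample_id: str
    locus_id: str
    tool_id: str
    allele1: Optional[int] = None
    allele2: Optional[int] = None
    ci: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        for a in (self.allele1, self.allele2):
            if a is not None and a < 0:
                raise ValueError(f"negative repeat count {a}")
        if self.allele1 is None and self.allele2 is not None:
            raise ValueError("allele2 set without allele1")

    @property
    def missing(self) -> bool:
        return self.allele1 is None and self.allele2 is None

    @property
    def alleles(self) -> tuple[int, ...]:
        """Called alleles (1 for hemizygous, 2 for diploid, 0 if missing)."""
        return tuple(a for a in (self.allele1, self.allele2) if a is not None)


@dataclass(frozen=True)
class OutlierResult:
    """An outlier test's p-value for one sample at one locus."""

    sample_id: str
    locus_id: str
    tool_id: str
    p_raw: Optional[float] = None
    p_adj: Optional[float] = None

    def __post_init__(self) -> None:
        for name, p in (("p_raw", self.p_raw), ("p_adj", self.p_adj)):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if (self.p_raw is not None and self.p_adj is not None
                and self.p_adj < self.p_raw - 1e-12):
            raise ValueError("adjusted p-value below raw p-value")

    @property
    def missing(self) -> bool:
        return self.p_raw is None and self.p_adj is None


@dataclass(frozen=True)
class UnifiedCall:
    """A binary full-mutation flag with provenance to its source record."""

    sample_id: str
    locus_id: str
    tool_id: str
    flag: Optional[int]  # 1, 0, or None for missing
    evidence: Union[GenotypeCall, OutlierResult, None] = None

    def __post_init__(self) -> None:
        if self.flag not in (0, 1, None):
            raise ValueError(f"flag must be 0, 1 or missing, got {self.flag}")


@dataclass
class LabeledMatrix:
    """Binary call matrix: one row per (sample, locus), one column per tool.

    ``data`` is indexed by a (sample, locus) MultiIndex with integer tool
    columns in the supplied order; ``labels`` is the aligned truth Series
    with values ``full_mutation`` / ``non_full_mutation``.  Rows containing
    any missing flag are removed during assembly and counted in
    ``n_dropped``.
    """

    data: pd.DataFrame
    labels: pd.Series
    tools: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise HarmonizeError("matrix and labels are misaligned")
        if self.data.index.has_duplicates:
            raise HarmonizeError("duplicate (sample, locus) row keys")
        if self.data.isna().any().any():
            raise HarmonizeError("assembled matrix contains missing entries")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self):
        return self.data.to_numpy(dtype=int)

    @property
    def y(self):
        return (self.labels == LABEL_FM).to_numpy(dtype=int)

    def subset_rows(self, positions: Sequence[int]) -> "LabeledMatrix":
        return LabeledMatrix(self.data.iloc[list(positions)],
                             self.labels.iloc[list(positions)], self.tools)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "locus", self.data.index.get_level_values(1))
        out.insert(0, "sample", self.data.index.get_level_values(0))
        out["label"] = self.labels.to_numpy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledMatrix":
        df = pd.read_csv(path, sep="\t")
        tools = tuple(c for c in df.columns
                      if c not in ("sample", "locus", "label"))
        idx = pd.MultiIndex.from_arrays(
            [df["sample"], df["locus"]], names=["sample", "locus"])
        data = df[list(tools)].set_axis(idx)
        labels = df["label"].set_axis(idx)
        return cls(data, labels, tools)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def _parse_genotype_string(geno: str, context: str) -> tuple[Optional[int], ...]:
    parts = geno.split("/")
    if not 1 <= len(parts) <= 2:
        raise HarmonizeError(f"{context}: malformed genotype {geno!r}")
    alleles = []
    for part in parts:
        part = part.strip()
        if part in (".", ""):
            alleles.append(None)
            continue
        try:
            alleles.append(int(part))
        except ValueError as exc:
            raise HarmonizeError(
                f"{context}: malformed genotype {geno!r}") from exc
    return tuple(alleles)


def _parse_eh_json(path: Path, tool_id: str) -> list[GenotypeCall]:
    doc = json.loads(path.read_text())
    sample_id = doc.get("SampleId") or doc.get("SampleParameters", {}).get(
        "SampleId")
    if sample_id is None:
        raise HarmonizeError(f"{path}: no SampleId")
    calls = []
    for locus_id, locus_res in doc.get("LocusResults", {}).items():
        variants = locus_res.get("Variants", {})
        var = variants.get(locus_id) or next(iter(variants.values()), None)
        geno = None if var is None else var.get("Genotype")
        if geno is None:
            calls.append(GenotypeCall(sample_id, locus_id, tool_id))
            continue
        alleles = _parse_genotype_string(geno, f"{path}:{locus_id}")
        ci = None
        ci_str = var.get("GenotypeConfidenceInterval")
        if ci_str:
            try:
                ci = tuple(
                    (int(lo), int(hi))
                    for lo, hi in (part.split("-") for part in
                                   ci_str.split("/")))
            except ValueError:
                ci = None
        a1 = alleles[0]
        a2 = alleles[1] if len(alleles) == 2 else None
        if a1 is None and a2 is not None:
            a1, a2 = a2, None
        calls.append(GenotypeCall(sample_id, locus_id, tool_id, a1, a2, ci))
    return calls


# FORMAT field carrying the per-allele repeat counts, and its separator.
_VCF_FIELD = {"gangstr": ("REPCN", ","), "tredparse": ("GB", "/"),
              "lobstr": ("GB", "/"), "hipstr": ("GB", "/"),
              "repeatseq": ("GB", "/")}


def _parse_vcf(path: Path, tool_id: str) -> list[GenotypeCall]:
    field_name, sep = _VCF_FIELD[tool_id]
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise HarmonizeError(
                f"{path}: expected a single-sample VCF, found {len(samples)}")
        sample_id = samples[0]
        for rec in vcf:
            locus_id = rec.id
            if locus_id is None:
                raise HarmonizeError(
                    f"{path}: record at {rec.chrom}:{rec.pos} has no locus ID")
            raw = rec.samples[sample_id].get(field_name)
            if raw is None or raw in (".", (".",)):
                calls.append(GenotypeCall(sample_id, locus_id, tool_id))
                continue
            if isinstance(raw, tuple):
                raw = sep.join(str(x) for x in raw if x is not None)
            geno = str(raw).replace(sep, "/")
            alleles = _parse_genotype_string(geno, f"{path}:{locus_id}")
            present = tuple(a for a in alleles if a is not None)
            if not present:
                calls.append(GenotypeCall(sample_id, locus_id, tool_id))
                continue
            a1 = present[0]
            a2 = present[1] if len(present) == 2 else None
            calls.append(GenotypeCall(sample_id, locus_id, tool_id, a1, a2))
    return calls


def parse_genotyper_output(path: str | Path, dialect: str,
                           ) -> list[GenotypeCall]:
    """Parse one genotyper output file into :class:`GenotypeCall` records.

    ``dialect`` names the tool whose field contract applies (see the module
    docstring); ``eh_v2``/``eh_v3`` read JSON, the rest read single-sample
    VCF.  Loci absent from a file simply produce no call; a present record
    with an uncallable genotype produces a missing call.
    """
    path = Path(path)
    if dialect in ("eh_v2", "eh_v3"):
        return _parse_eh_json(path, dialect)
    if dialect in _VCF_FIELD:
        return _parse_vcf(path, dialect)
    raise HarmonizeError(f"unknown genotyper dialect {dialect!r}")


def parse_outlier_output(path: str | Path, dialect: str) -> list[OutlierResult]:
    """Parse an outlier-test table (STRetch-style adjusted, exSTRa-style raw).

    STRetch tables carry a ``p_adj`` column (already multiple-testing
    adjusted by the tool); exSTRa tables carry raw ``p`` values and leave
    ``p_adj`` unset for downstream adjustment.
    """
    if dialect not in OUTLIER_TOOLS:
        raise HarmonizeError(f"unknown outlier dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample", "locus", "p_adj" if dialect == "stretch" else "p"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise HarmonizeError(
            f"{path}: missing columns {sorted(missing_cols)}")
    results = []
    for row in df.itertuples(index=False):
        if dialect == "stretch":
            p_adj = getattr(row, "p_adj")
            p_adj = None if pd.isna(p_adj) else float(p_adj)
            p_raw = getattr(row, "p", None)
            p_raw = None if p_raw is None or pd.isna(p_raw) else float(p_raw)
            results.append(OutlierResult(str(row.sample), str(row.locus),
                                         dialect, p_raw, p_adj))
        else:
            p_raw = getattr(row, "p")
            p_raw = None if pd.isna(p_raw) else float(p_raw)
            results.append(OutlierResult(str(row.sample), str(row.locus),
                                         dialect, p_raw, None))
    return results


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

_MT_METHOD = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


def adjust_pvalues(p_raw: Sequence[float], method: str = "bh") -> list[float]:
    """Adjust p-values for multiple testing (order-preserving, clipped).

    ``bh`` is the Benjamini-Hochberg step-up FDR procedure, ``holm`` the
    step-down Bonferroni, ``bonferroni`` the plain product bound.
    """
    if method not in _MT_METHOD:
        raise ValueError(f"unknown adjustment method {method!r}")
    p = list(p_raw)
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value {v} outside [0, 1]")
    if not p:
        return []
    adjusted = multipletests(p, method=_MT_METHOD[method])[1]
    return [min(1.0, float(v)) for v in adjusted]


def adjust_outlier_results(results: Sequence[OutlierResult],
                           method: str = "bh") -> list[OutlierResult]:
    """Fill missing ``p_adj`` fields, adjusting jointly per tool across the
    whole run (all sample-locus tests of that tool form one family).

    Results that already carry an adjusted p-value (e.g. STRetch output)
    are passed through unchanged.
    """
    by_tool: dict[str, list[int]] = {}
    out = list(results)
    for i, res in enumerate(results):
        if res.p_adj is None and res.p_raw is not None:
            by_tool.setdefault(res.tool_id, []).append(i)
    for tool_id, idxs in by_tool.items():
        adjusted = adjust_pvalues([out[i].p_raw for i in idxs], method)
        for i, p_adj in zip(idxs, adjusted):
            res = out[i]
            out[i] = OutlierResult(res.sample_id, res.locus_id, res.tool_id,
                                   res.p_raw, p_adj)
    return out


# ---------------------------------------------------------------------------
# Binarization and matrix assembly
# ---------------------------------------------------------------------------

def binarize(call: Union[GenotypeCall, OutlierResult],
             catalog: Mapping[str, LocusDefinition],
             mode: str = "default", alpha: float = 0.05) -> UnifiedCall:
    """Reduce one tool record to a binary full-mutation flag.

    Genotyper calls flag 1 when at least one allele classifies full-mutation
    under *mode*; outlier calls flag 1 when the adjusted p-value is strictly
    below *alpha*.  Missing inputs stay missing.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if call.locus_id not in catalog:
        raise HarmonizeError(f"unknown locus {call.locus_id!r}")
    if isinstance(call, GenotypeCall):
        if call.missing:
            return UnifiedCall(call.sample_id, call.locus_id, call.tool_id,
                               None, call)
        cls = classify_sample(catalog[call.locus_id], call.alleles, mode)
        flag = 1 if cls.flag else 0
    else:
        if call.p_adj is None:
            return UnifiedCall(call.sample_id, call.locus_id, call.tool_id,
                               None, call)
        flag = 1 if call.p_adj < alpha else 0
    return UnifiedCall(call.sample_id, call.locus_id, call.tool_id, flag, call)


def binarize_all(calls: Iterable[Union[GenotypeCall, OutlierResult]],
                 catalog: Mapping[str, LocusDefinition],
                 mode: str = "default", alpha: float = 0.05,
                 adjust_method: str = "bh") -> list[UnifiedCall]:
    """Binarize a mixed call set, adjusting raw outlier p-values first."""
    calls = list(calls)
    outliers = [c for c in calls if isinstance(c, OutlierResult)]
    adjusted = iter(adjust_outlier_results(outliers, adjust_method))
    unified = []
    for call in calls:
        if isinstance(call, OutlierResult):
            call = next(adjusted)
        unified.append(binarize(call, catalog, mode, alpha))
    return unified


def build_labeled_matrix(calls: Iterable[UnifiedCall],
                         truth: Mapping[tuple[str, str], str],
                         tools: Sequence[str]) -> LabeledMatrix:
    """Assemble unified calls into a labeled binary matrix.

    One row per (sample, locus) key observed in *calls*; columns follow the
    supplied tool order.  Rows with any missing flag among the selected
    tools are dropped (and counted), matching the training-set construction
    in which incomplete tool coverage disqualifies a row.

    Raises
    ------
    HarmonizeError
        If a surviving row key has no truth label.
    """
    tools = tuple(tools)
    cells: dict[tuple[str, str], dict[str, Optional[int]]] = {}
    for call in calls:
        if call.tool_id not in tools:
            continue
        row = cells.setdefault((call.sample_id, call.locus_id), {})
        if call.tool_id in row:
            raise HarmonizeError(
                f"duplicate call for {(call.sample_id, call.locus_id, call.tool_id)}")
        row[call.tool_id] = call.flag
    keys, rows, labels, n_dropped = [], [], [], 0
    for key in sorted(cells):
        row = cells[key]
        flags = [row.get(t) for t in tools]
        if any(f is None for f in flags):
            n_dropped += 1
            continue
        if key not in truth:
            raise HarmonizeError(f"no truth label for row {key}")
        label = truth[key]
        if label not in (LABEL_FM, LABEL_NON_FM):
            raise HarmonizeError(f"unknown label {label!r} for row {key}")
        keys.append(key)
        rows.append(flags)
        labels.append(label)
    if keys:
        idx = pd.MultiIndex.from_tuples(keys, names=["sample", "locus"])
    else:
        idx = pd.MultiIndex.from_arrays([[], []], names=["sample", "locus"])
    data = pd.DataFrame(rows, index=idx, columns=list(tools), dtype=int)
    return LabeledMatrix(data, pd.Series(labels, index=idx, dtype=object),
                         tools, n_dropped)
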