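"""Candidate k-mer enumeration, binding prediction, DAI, and binder tiers.

Binding prediction is behind a small adapter contract — a predictor maps a
batch of peptides plus an HLA allele to IC50 values (nM) in the same order —
so established predictors (the IEDB class I/II suites, MHCflurry) can be
plugged in as out-of-process commands without shipping their models. A
deterministic built-in "toy" predictor makes the whole pipeline testable and
reproducible without external binaries; it is a fixed position-weight scheme,
not a trained affinity model.

IC50 tiers follow the conventional cutoffs: strong < 50 nM, intermediate
50–250 nM, weak 250–500 nM (exclusive), non-binding >= 500 nM. The
differential agretopicity index (DAI) is the wild-type/mutant IC50 fold
change: DAI > 1 flags a mutation that improves HLA binding.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
import shlex
import subprocess
from dataclasses import dataclass
from functools import lru_cache
from typing import Protocol, Sequence

from neoforge.peptides import NeoepitopeWindow

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CLASS_I_GENES = frozenset({"A", "B", "C", "E", "F", "G"})
CLASS_II_GENES = frozenset(
    {"DRA", "DRB1", "DRB3", "DRB4", "DRB5", "DQA1", "DQB1", "DPA1", "DPB1"}
)

DEFAULT_LENGTHS = {"I": (8, 9, 10, 11), "II": (15,)}

_ALLELE_RE = re.compile(r"^([A-Z]+[0-9]*)[*_]?(\d{2,3}):?(\d{2,3})$")


@dataclass(frozen=True)
class HlaAllele:
    """A normalized HLA allele name with its inferred MHC class."""

    name: str
    mhc_class: str  # "I" or "II"

    def __str__(self) -> str:
        return self.name


def parse_allele(raw: str) -> HlaAllele:
    """Normalize an HLA allele string.

    Accepts common spellings (``HLA-A*02:01``, ``A*0201``, ``A0201``,
    ``DRB1_0101``) and produces the canonical class I form ``HLA-A*02:01``
    or class II form ``DRB1*01:01``. Normalization is idempotent.
    """
    token = raw.strip().upper()
    token = token.removeprefix("HLA-").removeprefix("HLA")
    m = _ALLELE_RE.match(token)
    if not m:
        raise ValueError(f"unrecognized HLA allele: {raw!r}")
    gene, group, protein = m.groups()
    if gene in CLASS_I_GENES:
        return HlaAllele(f"HLA-{gene}*{group}:{protein}", "I")
    if gene in CLASS_II_GENES:
        return HlaAllele(f"{gene}*{group}:{protein}", "II")
    raise ValueError(f"unknown HLA gene {gene!r} in allele {raw!r}")


@dataclass
class BindingCall:
    """A single peptide–allele binding prediction."""

    peptide: str
    allele: HlaAllele
    ic50_nm: float
    method: str

    def __post_init__(self) -> None:
        if self.ic50_nm <= 0:
            raise ValueError("ic50_nm must be positive")


@dataclass
class AnnotatedCandidate:
    """A candidate neoepitope k-mer with scores, DAI and binder tier."""

    window: NeoepitopeWindow
    mut_peptide: str
    wt_peptide: str | None
    allele: HlaAllele
    ic50_mut: float
    ic50_wt: float | None
    dai: float | None
    category: str
    offset: int = 0  # 0-based k-mer offset within the window
    expression_flag: str | None = None

    @property
    def gene_symbol(self) -> str:
        return self.window.gene_symbol

    @property
    def aa_change(self) -> str:
        return self.window.label


# --- predictor registry ---------------------------------------------------

@dataclass(frozen=True)
class MethodInfo:
    """Descriptor of a binding-prediction method behind the adapter contract."""

    name: str
    mhc_class: str
    source: str  # "IEDB", "MHCflurry", or "builtin"
    internal: bool = False  # builtin stand-in, not a published predictor


_METHODS = [
    MethodInfo("NetMHC", "I", "IEDB"),
    MethodInfo("NetMHCpan", "I", "IEDB"),
    MethodInfo("NetMHCcons", "I", "IEDB"),
    MethodInfo("NetMHCstabpan", "I", "IEDB"),
    MethodInfo("PickPocket", "I", "IEDB"),
    MethodInfo("SMM", "I", "IEDB"),
    MethodInfo("SMMPMBEC", "I", "IEDB"),
    MethodInfo("MHCflurry", "I", "MHCflurry"),
    MethodInfo("NetMHCIIpan", "II", "IEDB"),
    MethodInfo("NN-align", "II", "IEDB"),
    MethodInfo("SMM-align", "II", "IEDB"),
    MethodInfo("Sturniolo", "II", "IEDB"),
    MethodInfo("toy", "I", "builtin", internal=True),
    MethodInfo("toy", "II", "builtin", internal=True),
]


def method_registry() -> tuple[list[MethodInfo], list[MethodInfo]]:
    """Registered prediction methods as (class I list, class II list).

    Class I holds the seven IEDB methods plus MHCflurry; class II the four
    IEDB methods. The built-in deterministic "toy" method appears in both
    lists flagged ``internal``.
    """
    class_i = [m for m in _METHODS if m.mhc_class == "I"]
    class_ii = [m for m in _METHODS if m.mhc_class == "II"]
    return class_i, class_ii


def lookup_method(name: str, mhc_class: str | None = None) -> MethodInfo:
    for m in _METHODS:
        if m.name.lower() == name.lower() and (mhc_class in (None, m.mhc_class)):
            return m
    raise KeyError(f"unknown prediction method: {name}")


# --- predictors -----------------------------------------------------------

class Predictor(Protocol):
    """Adapter contract: batch of peptides + allele -> IC50 list (nM),
    order-preserving."""

    name: str

    def predict_batch(
        self, peptides: Sequence[str], allele: HlaAllele
    ) -> list[float]: ...


_MAX_TOY_LEN = 15
_LOG_MAX_IC50 = math.log(50000.0)


@lru_cache(maxsize=64)
def _toy_weights(allele_name: str) -> tuple[dict[str, float], ...]:
    """Fixed per-allele position weights in [0, 1), derived from MD5 so they
    are stable across runs, platforms and Python hash randomization."""
    table = []
    for pos in range(_MAX_TOY_LEN):
        row = {}
        for aa in AMINO_ACIDS:
            digest = hashlib.md5(f"{allele_name}|{pos}|{aa}".encode()).digest()
            row[aa] = int.from_bytes(digest[:8], "big") / 2**64
        table.append(row)
    return tuple(table)


def toy_predict(peptide: str, allele: HlaAllele) -> float:
    """Deterministic stand-in IC50 (nM) from a fixed position-weight scheme.

    The mean per-position weight s in (0, 1) is mapped to ``50000**s``, so
    outputs lie in (1, 50000] nM and changing any single residue — anchor
    positions included — changes the value.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residue(s) in peptide: {sorted(bad)}")
    weights = _toy_weights(allele.name)
    score = sum(
        weights[i % _MAX_TOY_LEN][aa] for i, aa in enumerate(peptide)
    ) / len(peptide)
    return math.exp(_LOG_MAX_IC50 * score)


class ToyPredictor:
    """Built-in deterministic predictor implementing the adapter contract."""

    name = "toy"

    def predict_batch(
        self, peptides: Sequence[str], allele: HlaAllele
    ) -> list[float]:
        return [toy_predict(p, allele) for p in peptides]


class CommandPredictor:
    """Out-of-process adapter: runs a user-configured command template.

    The template receives ``{allele}`` and ``{length}`` placeholders and the
    peptides one per line on stdin; it must print one IC50 (nM) per input
    peptide, in order. This is how licensed external predictors (NetMHC*
    suites, MHCflurry) are attached without shipping their models.
    """

    def __init__(self, name: str, template: str):
        self.name = name
        self.template = template

    def predict_batch(
        self, peptides: Sequence[str], allele: HlaAllele
    ) -> list[float]:
        if not peptides:
            return []
        length = len(peptides[0])
        cmd = shlex.split(self.template.format(allele=allele.name, length=length))
        proc = subprocess.run(
            cmd, input="\n".join(peptides) + "\n",
            capture_output=True, text=True, check=True,
        )
        values = [float(tok) for tok in proc.stdout.split()]
        if len(values) != len(peptides):
            raise RuntimeError(
                f"{self.name}: expected {len(peptides)} scores, got {len(values)}"
            )
        return values


def get_predictor(method: str, command_templates: dict[str, str] | None = None) -> Predictor:
    """Instantiate the predictor for a registered method.

    ``toy`` is built in; any other method needs a command template mapping
    (method name -> shell template) supplied via configuration.
    """
    info = lookup_method(method)
    if info.internal:
        return ToyPredictor()
    if command_templates and info.name in command_templates:
        return CommandPredictor(info.name, command_templates[info.name])
    raise ValueError(
        f"method {info.name!r} requires an external command template; "
        "only the built-in 'toy' predictor ships executable"
    )


# --- scoring --------------------------------------------------------------

def compute_dai(ic50_wt: float, ic50_mut: float) -> float:
    """Differential agretopicity index: wild-type/mutant IC50 fold change.

    Values above 1 mean the mutant peptide is predicted to bind better than
    its wild-type counterpart.
    """
    if ic50_wt <= 0 or ic50_mut <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_wt / ic50_mut


def classify_binder(ic50_nm: float) -> str:
    """Affinity tier for a predicted IC50: strong (< 50 nM), intermediate
    ([50, 250] nM), weak ((250, 500) nM), non-binding (>= 500 nM)."""
    if ic50_nm <= 0:
        raise ValueError("ic50_nm must be positive")
    if ic50_nm < 50:
        return "strong"
    if ic50_nm <= 250:
        return "intermediate"
    if ic50_nm < 500:
        return "weak"
    return "non-binding"


def enumerate_candidate_peptides(
    window: NeoepitopeWindow, k: int
) -> list[tuple[str, str | None, int]]:
    """All k-mers of the mutant window that cover at least one altered
    residue, left to right, as (mut_peptide, wt_peptide or None, offset).

    The wild-type peptide is the same-offset k-mer of the wild-type window
    and exists only when the window carries one (missense). A k larger than
    the window yields an empty list with a warning.
    """
    m = len(window.mut_window)
    if k > m:
        logger.warning(
            "k=%d exceeds window length %d for %s; no candidates",
            k, m, window.label,
        )
        return []
    alt_start = window.mut_index
    alt_end = window.mut_index + window.altered_span - 1
    out = []
    for offset in range(m - k + 1):
        lo, hi = offset + 1, offset + k  # 1-based residue span of this k-mer
        if hi < alt_start or lo > alt_end:
            continue
        mut_pep = window.mut_window[offset : offset + k]
        wt_pep = None
        if window.wt_window is not None:
            wt_pep = window.wt_window[offset : offset + k]
        out.append((mut_pep, wt_pep, offset))
    return out


def annotate_candidates(
    windows: Sequence[NeoepitopeWindow],
    alleles: Sequence[HlaAllele],
    lengths: Sequence[int] | dict[str, Sequence[int]] | None = None,
    method: str = "toy",
    predictor: Predictor | None = None,
    batch_size: int = 64,
) -> list[AnnotatedCandidate]:
    """Score every covering k-mer of every window against every allele.

    Wild-type peptides are scored in the same pass with the same method, the
    DAI and binder tier attached. Results are returned in a deterministic
    order independent of the batch size and of the input window order. A
    failing predictor batch is recorded and skipped; other batches are
    unaffected.
    """
    if predictor is None:
        predictor = get_predictor(method)
    if lengths is None:
        lengths = dict(DEFAULT_LENGTHS)
    if not isinstance(lengths, dict):
        lengths = {"I": tuple(lengths), "II": tuple(lengths)}

    ordered = sorted(
        windows,
        key=lambda w: (w.sample_id, w.gene_symbol, w.transcript_id, w.label),
    )
    # gather peptides per (allele, length) so batches hold same-length peptides
    tasks: list[tuple[NeoepitopeWindow, HlaAllele, str, str | None, int]] = []
    for allele in sorted(alleles, key=lambda a: a.name):
        for window in ordered:
            for k in sorted(lengths.get(allele.mhc_class, ())):
                for mut_pep, wt_pep, offset in enumerate_candidate_peptides(window, k):
                    tasks.append((window, allele, mut_pep, wt_pep, offset))

    # score unique (peptide, allele) pairs in batches
    scores: dict[tuple[str, str], float] = {}
    by_allele_len: dict[tuple[HlaAllele, int], list[str]] = {}
    for window, allele, mut_pep, wt_pep, _ in tasks:
        for pep in (mut_pep, wt_pep):
            if pep is not None and (pep, allele.name) not in scores:
                scores[(pep, allele.name)] = math.nan
                by_allele_len.setdefault((allele, len(pep)), []).append(pep)
    for (allele, _), peptides in by_allele_len.items():
        for i in range(0, len(peptides), batch_size):
            batch = peptides[i : i + batch_size]
            try:
                values = predictor.predict_batch(batch, allele)
            except Exception as exc:  # noqa: BLE001 - per-batch isolation
                logger.error("predictor %s failed on a batch of %d peptides: %s",
                             predictor.name, len(batch), exc)
                for pep in batch:
                    del scores[(pep, allele.name)]
                continue
            for pep, val in zip(batch, values):
                scores[(pep, allele.name)] = val

    candidates = []
    for window, allele, mut_pep, wt_pep, offset in tasks:
        ic50_mut = scores.get((mut_pep, allele.name))
        if ic50_mut is None or math.isnan(ic50_mut):
            continue
        ic50_wt = scores.get((wt_pep, allele.name)) if wt_pep is not None else None
        if ic50_wt is not None and math.isnan(ic50_wt):
            ic50_wt = None
        dai = compute_dai(ic50_wt, ic50_mut) if ic50_wt is not None else None
        candidates.append(AnnotatedCandidate(
            window=window, mut_peptide=mut_pep,
            wt_peptide=wt_pep if ic50_wt is not None else wt_pep,
            allele=allele, ic50_mut=ic50_mut, ic50_wt=ic50_wt,
            dai=dai, category=classify_binder(ic50_mut), offset=offset,
        ))
    candidates.sort(key=lambda c: (
        c.window.sample_id, c.window.gene_symbol, c.window.transcript_id,
        c.window.label, c.allele.name, len(c.mut_peptide), c.offset,
    ))
    return candidates
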