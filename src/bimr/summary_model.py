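"""GWAS summary statistics: data model, I/O, orientation and allele harmonization.

A study's summary statistics are a list of :class:`VariantAssociation` records,
one per SNP, in a GWAS-SSF-like tab-delimited format.  Two-sample Mendelian
randomization joins an exposure study and an outcome study on variant ID and
must first make sure both betas refer to the same effect allele — that is the
job of :func:`harmonize`.  Palindromic SNPs (A/T or C/G) are strand-ambiguous:
when the effect-allele frequency is missing or too close to 0.5 in either
study they are dropped; otherwise strand is inferred from frequency agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, DataError, ParseError

__all__ = [
    "VariantAssociation",
    "LDPair",
    "HarmonizedInstrument",
    "SUMSTATS_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld",
    "orient_to_trait_increasing",
    "harmonize",
]

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))

SUMSTATS_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is in trait units per copy of ``effect_allele``; ``eaf`` is the
    effect-allele frequency and may be ``None`` when the source study did not
    report it (which forces palindromic variants to be dropped downstream).
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise DataError(
                f"{self.variant_id}: alleles must be single nucleotides A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise DataError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise DataError(f"{self.variant_id}: pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DataError(f"{self.variant_id}: eaf must lie in [0, 1], got {self.eaf}")
        if self.n <= 0:
            raise DataError(f"{self.variant_id}: n must be a positive integer, got {self.n}")
        if self.position < 1:
            raise DataError(f"{self.variant_id}: position must be >= 1, got {self.position}")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_SETS


@dataclass(frozen=True)
class LDPair:
    """Pairwise linkage disequilibrium (r^2) between two variants."""

    variant_a: str
    variant_b: str
    r2: float

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise DataError(f"r2 must lie in [0, 1], got {self.r2}")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP joined across exposure and outcome studies with aligned alleles.

    ``ratio`` is the per-SNP Wald ratio beta_outcome / beta_exposure and
    ``ratio_se`` its first-order delta-method standard error
    se_outcome / |beta_exposure|; both are ``nan`` for dropped variants or
    when the exposure beta is zero.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    ratio: float
    ratio_se: float
    status: str  # kept | flipped | dropped_palindromic | dropped_mismatch


def _resolve_columns(columns: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical names to the file's actual column names."""
    mapping = {c: c for c in SUMSTATS_COLUMNS}
    if column_map:
        mapping.update(column_map)
    missing = [c for c in SUMSTATS_COLUMNS if mapping[c] not in columns]
    if missing:
        raise ConfigurationError(
            "missing required column(s): "
            + ", ".join(f"{c} (looked for {mapping[c]!r})" for c in missing)
        )
    return mapping


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None
) -> list[VariantAssociation]:
    """Read a tab-delimited summary-statistics table.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Optional mapping from canonical column names (``beta``, ``se``, ...)
        to the names actually present in the file.

    Returns records in file order; malformed rows raise :class:`ParseError`
    naming the offending data row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    mapping = _resolve_columns(list(frame.columns), column_map)
    records: list[VariantAssociation] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        try:
            eaf_raw = raw[mapping["eaf"]]
            records.append(
                VariantAssociation(
                    variant_id=str(raw[mapping["variant_id"]]),
                    chromosome=str(raw[mapping["chromosome"]]),
                    position=int(raw[mapping["position"]]),
                    effect_allele=str(raw[mapping["effect_allele"]]).upper(),
                    other_allele=str(raw[mapping["other_allele"]]).upper(),
                    eaf=None if pd.isna(eaf_raw) else float(eaf_raw),
                    beta=float(raw[mapping["beta"]]),
                    se=float(raw[mapping["se"]]),
                    pvalue=float(raw[mapping["pvalue"]]),
                    n=int(raw[mapping["n"]]),
                )
            )
        except (DataError, ValueError, TypeError) as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    return records


def write_summary_stats(records: Iterable[VariantAssociation], path) -> None:
    """Write records in the canonical tab-delimited format.

    Numeric fields use shortest round-trip representation (``repr``), so
    ``read_summary_stats(write_summary_stats(x)) == x`` bit-for-bit; a missing
    eaf is serialized as ``NA``.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chromosome": r.chromosome,
                "position": r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "NA" if r.eaf is None else repr(float(r.eaf)),
                "beta": repr(float(r.beta)),
                "se": repr(float(r.se)),
                "pvalue": repr(float(r.pvalue)),
                "n": r.n,
            }
        )
    frame = pd.DataFrame(rows, columns=list(SUMSTATS_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_ld(path) -> list[LDPair]:
    """Read a pairwise LD table.

    Accepts the canonical tab-delimited ``variant_a variant_b r2`` header or a
    whitespace-delimited table with PLINK-style columns ``SNP_A SNP_B R2``.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in frame.columns}
    try:
        a = cols.get("variant_a") or cols["snp_a"]
        b = cols.get("variant_b") or cols["snp_b"]
        r2 = cols.get("r2") or cols["r2"]
    except KeyError as exc:
        raise ConfigurationError(
            f"LD table must have columns variant_a/variant_b/r2 or SNP_A/SNP_B/R2, got {list(frame.columns)}"
        ) from exc
    return [
        LDPair(str(row[a]), str(row[b]), float(row[r2]))
        for _, row in frame.iterrows()
    ]


def orient_to_trait_increasing(
    records: Iterable[VariantAssociation],
) -> list[VariantAssociation]:
    """Re-express every association so the beta is non-negative.

    For a negative beta the effect and other alleles are swapped, the beta
    negated and the eaf replaced by 1 - eaf; p-values and SEs are untouched.
    Idempotent.
    """
    out = []
    for r in records:
        if r.beta < 0:
            out.append(
                replace(
                    r,
                    beta=-r.beta,
                    effect_allele=r.other_allele,
                    other_allele=r.effect_allele,
                    eaf=None if r.eaf is None else 1.0 - r.eaf,
                )
            )
        else:
            out.append(r)
    return out


def _check_unique(records: Sequence[VariantAssociation], label: str) -> dict[str, VariantAssociation]:
    by_id: dict[str, VariantAssociation] = {}
    for r in records:
        if r.variant_id in by_id:
            raise DataError(f"duplicate variant_id {r.variant_id!r} in {label} study")
        by_id[r.variant_id] = r
    return by_id


def _complemented(e: str, o: str) -> tuple[str, str]:
    return _COMPLEMENT[e], _COMPLEMENT[o]


def _in_window(eaf: float | None, window: tuple[float, float]) -> bool:
    return eaf is None or window[0] <= eaf <= window[1]


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> list[HarmonizedInstrument]:
    """Align outcome-study alleles to the exposure study's effect allele.

    For each variant shared between the two studies:

    * alleles identical -> ``kept``;
    * alleles swapped -> outcome beta negated, eaf inverted, ``flipped``;
    * strand-complement labelling (A<->T, C<->G) -> relabel, then as above;
    * palindromic (A/T or C/G) variants are resolved through effect-allele
      frequency: if the eaf is missing or falls inside
      ``palindromic_eaf_window`` in either study the variant is
      ``dropped_palindromic``, otherwise strand is inferred from whether the
      two frequencies fall on the same side of 0.5;
    * anything else -> ``dropped_mismatch``.

    The output order follows the exposure table.  ``status == "flipped"``
    means the reported outcome beta/eaf are inverted relative to the input.
    """
    exp_by_id = _check_unique(exposure, "exposure")
    out_by_id = _check_unique(outcome, "outcome")

    results: list[HarmonizedInstrument] = []
    for vid, ex in exp_by_id.items():
        if vid not in out_by_id:
            continue
        ou = out_by_id[vid]
        exp_alleles = (ex.effect_allele, ex.other_allele)
        out_alleles = (ou.effect_allele, ou.other_allele)

        status: str | None = None
        n_flips = 0
        if ex.is_palindromic:
            if frozenset(out_alleles) != frozenset(exp_alleles):
                status = "dropped_mismatch"
            elif _in_window(ex.eaf, palindromic_eaf_window) or _in_window(
                ou.eaf, palindromic_eaf_window
            ):
                status = "dropped_palindromic"
            else:
                # Align labels first, then infer strand from eaf agreement.
                n_flips = 0 if out_alleles == exp_alleles else 1
                eaf_out_aligned = ou.eaf if n_flips == 0 else 1.0 - ou.eaf
                if (ex.eaf < 0.5) != (eaf_out_aligned < 0.5):
                    n_flips += 1  # opposite strand: one extra flip
        else:
            if out_alleles == exp_alleles:
                n_flips = 0
            elif out_alleles == exp_alleles[::-1]:
                n_flips = 1
            else:
                comp = _complemented(*out_alleles)
                if comp == exp_alleles:
                    n_flips = 0
                elif comp == exp_alleles[::-1]:
                    n_flips = 1
                else:
                    status = "dropped_mismatch"

        if status is None:
            flipped = n_flips % 2 == 1
            status = "flipped" if flipped else "kept"
            beta_out = -ou.beta if flipped else ou.beta
            eaf_out = None if ou.eaf is None else (1.0 - ou.eaf if flipped else ou.eaf)
            if abs(ex.beta) > 0:
                ratio = beta_out / ex.beta
                ratio_se = ou.se / abs(ex.beta)
            else:
                ratio = math.nan
                ratio_se = math.nan
            results.append(
                HarmonizedInstrument(
                    variant_id=vid,
                    beta_exposure=ex.beta,
                    se_exposure=ex.se,
                    beta_outcome=beta_out,
                    se_outcome=ou.se,
                    eaf_exposure=ex.eaf,
                    eaf_outcome=eaf_out,
                    ratio=ratio,
                    ratio_se=ratio_se,
                    status=status,
                )
            )
        else:
            results.append(
                HarmonizedInstrument(
                    variant_id=vid,
                    beta_exposure=ex.beta,
                    se_exposure=ex.se,
                    beta_outcome=ou.beta,
                    se_outcome=ou.se,
                    eaf_exposure=ex.eaf,
                    eaf_outcome=ou.eaf,
                    ratio=math.nan,
                    ratio_se=math.nan,
                    status=status,
                )
            )
    return results
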