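"""GWAS summary-statistic tables and instrument selection.

A summary-statistic record is one variant's association with one trait:
alleles, effect-allele frequency, effect size (beta) with standard error,
p-value and sample size.  Instruments for Mendelian randomization are picked
from such a table by a genome-wide significance filter (conventionally
P < 5e-8) followed by distance-based clumping so that each locus contributes
a single, strongest signal.

Clumping here is greedy and positional: within each chromosome the variant
with the smallest p-value is retained and every other variant within
``clump_window`` base pairs of it is removed; the procedure repeats on the
remainder.  Proper linkage-disequilibrium clumping needs a genotype reference
panel; the distance window (default 1 Mb) preserves the one-signal-per-locus
semantics without one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "RowError",
    "read_association_table",
    "write_association_table",
    "select_instruments",
    "write_instrument_set",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical column names, in output order
FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


class SumstatsError(ValueError):
    """Raised for unreadable input or invalid usage."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele effect in trait units; ``se`` its
    standard error.  ``chrom``/``pos`` (1-based) are needed only for
    clumping; ``eaf`` (effect-allele frequency) only for palindrome
    resolution; ``n`` only for bookkeeping.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str = ""
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SumstatsError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise SumstatsError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise SumstatsError("effect and other allele must differ")
        if not self.se > 0:
            raise SumstatsError(f"se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsError(f"eaf must be in [0,1], got {self.eaf}")


@dataclass(frozen=True)
class RowError:
    """A skipped input row: 1-based data-row number plus the reason."""

    row: int
    variant_id: str
    reason: str


@dataclass
class InstrumentSet:
    """Instruments for one exposure, with optional trait-level metadata.

    ``r2_total`` is the fraction of exposure variance jointly explained by
    the instruments (used by the F-statistic), ``n`` the exposure GWAS
    sample size.
    """

    exposure_name: str = ""
    unit: str = ""
    variants: list[VariantAssociation] = field(default_factory=list)
    r2_total: float | None = None
    n: int | None = None
    p_threshold: float | None = None
    clump_window: int | None = None

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def _norm_optional(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return value


def read_association_table(
    source: str | Path | IO[str],
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[VariantAssociation], list[RowError]]:
    """Read a delimited summary-statistic table.

    Parameters
    ----------
    source
        Path or open text stream; tab- or comma-delimited with a header row.
        Gzip-compressed paths are handled transparently.
    column_map
        Maps canonical field names (``variant_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pvalue``, optionally ``chrom``,
        ``pos``, ``eaf``, ``n``) to the file's column names.  Defaults to the
        identity mapping.
    sep
        Field separator; autodetected between tab and comma when ``None``.

    Returns
    -------
    (records, errors)
        Valid rows as :class:`VariantAssociation`, invalid rows as
        :class:`RowError` (reported, never silently dropped).
    """
    column_map = dict(column_map or {})
    try:
        df = pd.read_csv(
            source,
            sep=sep,
            engine="python" if sep is None else "c",
            dtype={column_map.get("chrom", "chrom"): str},
        )
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SumstatsError(f"unreadable summary-statistic table: {exc}") from exc

    for fld in MANDATORY:
        col = column_map.get(fld, fld)
        if col not in df.columns:
            raise SumstatsError(f"missing mandatory column {col!r} (field {fld!r})")

    records: list[VariantAssociation] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        get = lambda fld: _norm_optional(raw.get(column_map.get(fld, fld)))
        vid = get("variant_id")
        try:
            missing = [f for f in MANDATORY if get(f) is None]
            if missing:
                raise SumstatsError(f"missing mandatory field(s) {', '.join(missing)}")
            pos = get("pos")
            n = get("n")
            rec = VariantAssociation(
                variant_id=str(vid),
                effect_allele=str(get("effect_allele")).upper(),
                other_allele=str(get("other_allele")).upper(),
                beta=float(get("beta")),
                se=float(get("se")),
                pvalue=float(get("pvalue")),
                chrom="" if get("chrom") is None else str(get("chrom")),
                pos=None if pos is None else int(pos),
                eaf=None if get("eaf") is None else float(get("eaf")),
                n=None if n is None else int(n),
            )
        except (SumstatsError, TypeError) as exc:
            errors.append(RowError(row=i, variant_id="" if vid is None else str(vid), reason=str(exc)))
            continue
        records.append(rec)
    return records, errors


def write_association_table(
    records: Iterable[VariantAssociation],
    dest: str | Path | IO[str],
    sep: str = "\t",
) -> None:
    """Write records as a delimited table, preserving full float precision.

    Floats are written with ``repr`` so a write/read round trip is
    bit-identical; missing optional fields become ``NA``.
    """

    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    lines = [sep.join(FIELDS)]
    for rec in records:
        lines.append(sep.join(fmt(getattr(rec, f)) for f in FIELDS))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def select_instruments(
    associations: Sequence[VariantAssociation],
    p_threshold: float = 5e-8,
    clump_window: int = 1_000_000,
    exposure_name: str = "",
    unit: str = "",
    r2_total: float | None = None,
    n: int | None = None,
) -> InstrumentSet:
    """Significance-filter and distance-clump a table into an instrument set.

    Keeps associations with ``pvalue < p_threshold``; then, per chromosome,
    greedily retains the smallest-p variant (ties broken by lexicographic
    ``variant_id``) and discards all others within ``clump_window`` bp,
    repeating until exhausted.  ``clump_window = 0`` disables clumping.
    The result is independent of input row order.
    """
    if not (0 < p_threshold < 1):
        raise SumstatsError(f"p_threshold must be in (0,1), got {p_threshold}")
    if clump_window < 0:
        raise SumstatsError("clump_window must be >= 0")

    candidates = [a for a in associations if a.pvalue < p_threshold]
    seen: set[str] = set()
    for a in candidates:
        if a.variant_id in seen:
            raise SumstatsError(f"duplicate variant_id {a.variant_id!r}")
        seen.add(a.variant_id)

    if clump_window > 0:
        if any(a.pos is None for a in candidates):
            raise SumstatsError("clumping requires positions on all sub-threshold variants")
        retained: list[VariantAssociation] = []
        by_chrom: dict[str, list[VariantAssociation]] = {}
        for a in candidates:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom in sorted(by_chrom):
            pool = sorted(by_chrom[chrom], key=lambda a: (a.pvalue, a.variant_id))
            while pool:
                best = pool.pop(0)
                retained.append(best)
                pool = [a for a in pool if abs(a.pos - best.pos) > clump_window]
        retained.sort(key=lambda a: (a.pvalue, a.variant_id))
    else:
        retained = sorted(candidates, key=lambda a: (a.pvalue, a.variant_id))

    return InstrumentSet(
        exposure_name=exposure_name,
        unit=unit,
        variants=retained,
        r2_total=r2_total,
        n=n,
        p_threshold=p_threshold,
        clump_window=clump_window,
    )


def write_instrument_set(instruments: InstrumentSet, table_path: str | Path) -> None:
    """Write the instrument table plus a JSON sidecar with the selection
    parameters and counts (``<table>.json``)."""
    write_association_table(instruments.variants, table_path)
    sidecar = {
        "exposure_name": instruments.exposure_name,
        "unit": instruments.unit,
        "n_instruments": len(instruments),
        "p_threshold": instruments.p_threshold,
        "clump_window": instruments.clump_window,
        "r2_total": instruments.r2_total,
        "n": instruments.n,
    }
    Path(str(table_path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")
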