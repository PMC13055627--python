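"""Domain types and I/O for plot-level trial observations and taxa counts.

The experimental layout is a randomized block field trial: four humic-acid
application rates (a zero-rate control CK plus 3, 7.5 and 15 Mg ha-1) with
three replicate blocks, measured at two soil depth layers ("0-20cm",
"20-40cm") and a "plant" pseudo-layer holding above/below-ground traits.
One :class:`PlotObservation` is the atomic record: a single measured value
for one plot x indicator x layer.

Plot tables travel as long-format CSV with columns
``plot_id,block,treatment,layer,indicator,value`` (comma-separated, UTF-8,
"." decimal). Taxa count tables travel as TSV with a leading ``taxon_id``
column, one column per sample, and a trailing ``lineage`` column of
semicolon-delimited ranks (``k__...;p__...`` prefixes accepted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    FormatError,
    InsufficientReplicationError,
    ParseError,
    ValidationError,
)

MORE_IS_BETTER = "more_is_better"
LESS_IS_BETTER = "less_is_better"
CATEGORIES = ("chemical", "ion", "plant")

PLOT_COLUMNS = ["plot_id", "block", "treatment", "layer", "indicator", "value"]

#: depth strata used throughout; layers are opaque labels, never parsed
SOIL_LAYERS = ("0-20cm", "20-40cm")
PLANT_LAYER = "plant"

RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = {
    "k": "kingdom",
    "d": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


@dataclass(frozen=True)
class Treatment:
    """One amendment arm of the trial.

    Parameters
    ----------
    label : str
        Treatment code, e.g. ``"CK"`` or ``"HA7.5"``.
    rate : float
        Humic-acid application rate in Mg per ha; the control has rate 0.
    """

    label: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError(f"treatment {self.label!r}: rate must be >= 0")

    @property
    def is_control(self) -> bool:
        return self.rate == 0


DEFAULT_TREATMENTS: tuple[Treatment, ...] = (
    Treatment("CK", 0.0),
    Treatment("HA3", 3.0),
    Treatment("HA7.5", 7.5),
    Treatment("HA15", 15.0),
)


def validate_treatments(treatments: tuple[Treatment, ...] | list[Treatment]) -> None:
    """Check label uniqueness and that exactly one treatment is the control."""
    labels = [t.label for t in treatments]
    if len(set(labels)) != len(labels):
        raise ValidationError("treatment labels must be unique within a trial")
    n_control = sum(t.is_control for t in treatments)
    if n_control != 1:
        raise ValidationError(
            f"exactly one treatment must have rate 0 (control); found {n_control}"
        )


@dataclass(frozen=True)
class IndicatorSpec:
    """Identity, units, category and scoring direction of one indicator."""

    name: str
    units: str
    category: str
    direction: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"indicator {self.name!r}: category must be one of {CATEGORIES}"
            )
        if self.direction not in (MORE_IS_BETTER, LESS_IS_BETTER):
            raise ValidationError(
                f"indicator {self.name!r}: direction must be "
                f"{MORE_IS_BETTER!r} or {LESS_IS_BETTER!r}"
            )


@dataclass(frozen=True)
class PlotObservation:
    """One measured value for one plot x indicator x depth layer."""

    plot_id: str
    block: int
    treatment: str
    layer: str
    indicator: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(
                f"plot {self.plot_id!r} indicator {self.indicator!r}: value not finite"
            )


@dataclass(frozen=True)
class GroupSummary:
    """(group, n, mean, sd) — the representation agronomic tables print.

    ``sd`` is the sample standard deviation (n-1 denominator), matching the
    "means +/- standard deviation" convention.
    """

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.group!r}: n must be >= 1")
        if self.sd < 0:
            raise ValidationError(f"group {self.group!r}: sd must be >= 0")


# ---------------------------------------------------------------------------
# Indicator registry
# ---------------------------------------------------------------------------

def default_registry() -> dict[str, IndicatorSpec]:
    """Built-in indicator registry with field-standard scoring directions.

    Salinity/alkalinity indicators (pH, EC, Na+, Cl-, SO4 2-, HCO3-) score
    less-is-better: reducing them is an improvement on saline-alkali soil.
    Nutrient pools, organic matter and all plant traits score more-is-better.
    K+, Ca2+ and Mg2+ default to more-is-better (plant-available base
    cations) but are plain registry entries a user config can flip.

    Units for the water-soluble ions are conventional placeholders
    (``unverified``): the source tables print ion responses only in
    normalized form.
    """
    chem = [
        ("pH", "-", LESS_IS_BETTER),
        ("EC", "dS m-1", LESS_IS_BETTER),
        ("SOM", "g kg-1", MORE_IS_BETTER),
        ("TN", "g kg-1", MORE_IS_BETTER),
        ("TP", "g kg-1", MORE_IS_BETTER),
        ("TK", "g kg-1", MORE_IS_BETTER),
        ("AHN", "mg kg-1", MORE_IS_BETTER),
        ("AP", "mg kg-1", MORE_IS_BETTER),
        ("AK", "mg kg-1", MORE_IS_BETTER),
    ]
    ions = [
        ("Na+", LESS_IS_BETTER),
        ("Cl-", LESS_IS_BETTER),
        ("SO4-2", LESS_IS_BETTER),
        ("HCO3-", LESS_IS_BETTER),
        ("K+", MORE_IS_BETTER),
        ("Ca+2", MORE_IS_BETTER),
        ("Mg+2", MORE_IS_BETTER),
    ]
    plant = [
        "root_length",
        "root_surface_area",
        "root_volume",
        "root_biomass",
        "root_N",
        "root_P",
        "root_K",
        "shoot_N",
        "shoot_P",
        "shoot_K",
        "yield",
        "spike_number",
        "grain_number",
        "thousand_grain_weight",
    ]
    plant_units = {
        "root_length": "cm",
        "root_surface_area": "cm2",
        "root_volume": "cm3",
        "root_biomass": "g",
        "yield": "Mg ha-1",
        "spike_number": "m-2",
        "grain_number": "spike-1",
        "thousand_grain_weight": "g",
    }
    registry: dict[str, IndicatorSpec] = {}
    for name, units, direction in chem:
        registry[name] = IndicatorSpec(name, units, "chemical", direction)
    for name, direction in ions:
        registry[name] = IndicatorSpec(name, "g kg-1 (unverified)", "ion", direction)
    for name in plant:
        units = plant_units.get(name, "g kg-1")
        registry[name] = IndicatorSpec(name, units, "plant", MORE_IS_BETTER)
    return registry


def load_registry(path: str | Path) -> dict[str, IndicatorSpec]:
    """Read an indicator registry from a YAML mapping name -> spec fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise FormatError(f"{path}: registry must be a non-empty mapping")
    registry = {}
    for name, spec in raw.items():
        if not isinstance(spec, dict) or not {"units", "category", "direction"} <= set(spec):
            raise FormatError(
                f"{path}: indicator {name!r} must map to units/category/direction"
            )
        registry[str(name)] = IndicatorSpec(
            str(name), str(spec["units"]), str(spec["category"]), str(spec["direction"])
        )
    return registry


def save_registry(registry: dict[str, IndicatorSpec], path: str | Path) -> None:
    data = {
        spec.name: {
            "units": spec.units,
            "category": spec.category,
            "direction": spec.direction,
        }
        for spec in registry.values()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def sqi_indicators(registry: dict[str, IndicatorSpec]) -> list[IndicatorSpec]:
    """Soil-quality indicator set: water-soluble ions plus soil chemistry."""
    return [s for s in registry.values() if s.category in ("chemical", "ion")]


def pgi_indicators(registry: dict[str, IndicatorSpec]) -> list[IndicatorSpec]:
    """Plant-growth indicator set: root traits and root/shoot N, P, K.

    Yield and its components are excluded: they are responses the index is
    compared against, not inputs to it.
    """
    exclude = {"yield", "spike_number", "grain_number", "thousand_grain_weight"}
    return [
        s for s in registry.values() if s.category == "plant" and s.name not in exclude
    ]


# ---------------------------------------------------------------------------
# Plot table I/O
# ---------------------------------------------------------------------------

def read_plot_table(
    path: str | Path, registry: dict[str, IndicatorSpec]
) -> pd.DataFrame:
    """Read and validate a long-format plot observation CSV.

    Returns a DataFrame with the canonical columns, ``value`` as float.

    Raises
    ------
    FormatError
        if a required column is missing.
    ParseError
        for a non-numeric value (message carries the 1-based line number).
    ValidationError
        for unknown indicators or duplicate (plot_id, layer, indicator) keys.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[PLOT_COLUMNS].copy()

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values.astype(float))
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header row, one for 0- vs 1-based indexing
        raise ParseError(
            f"{path}: non-numeric or non-finite value {df['value'].iloc[idx]!r} "
            f"at line {idx + 2}"
        )
    df["value"] = values.astype(float)
    df["block"] = pd.to_numeric(df["block"], errors="raise").astype(int)

    unknown = sorted(set(df["indicator"]) - set(registry))
    if unknown:
        raise ValidationError(f"{path}: unknown indicator(s) not in registry: {unknown}")

    dup = df.duplicated(subset=["plot_id", "layer", "indicator"])
    if dup.any():
        rows = df.loc[dup, ["plot_id", "layer", "indicator"]].iloc[0].tolist()
        raise ValidationError(
            f"{path}: duplicate (plot_id, layer, indicator) key {tuple(rows)}"
        )
    return df.reset_index(drop=True)


def write_plot_table(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a plot observation table as canonical CSV.

    ``header_comment`` lines (without leading ``#``) are prepended as
    ``#``-comments; :func:`read_plot_table` skips them on the way back in.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, columns=PLOT_COLUMNS)


def observations_to_frame(obs: list[PlotObservation]) -> pd.DataFrame:
    return pd.DataFrame([o.__dict__ for o in obs], columns=PLOT_COLUMNS)


# ---------------------------------------------------------------------------
# Taxa table
# ---------------------------------------------------------------------------

@dataclass
class TaxaTable:
    """Samples x taxa count matrix with per-taxon rank annotations.

    ``counts`` is a samples-by-taxa integer DataFrame; ``lineage`` maps each
    taxon id to a (rank -> name) mapping with optional ranks.
    """

    counts: pd.DataFrame
    lineage: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("taxa counts must be non-negative")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValidationError("sample and taxon labels must be unique")
        extra = set(self.lineage) - set(self.counts.columns)
        if extra:
            raise ValidationError(f"lineage keys not in taxa: {sorted(extra)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


def parse_lineage(text: str, delimiter: str = ";") -> dict[str, str]:
    """Split a lineage string into a rank map.

    Tokens with a single-letter prefix (``p__Ascomycota``) are assigned by
    prefix; unprefixed tokens are assigned positionally kingdom..species.
    Empty tokens (``p__``) are dropped.
    """
    ranks: dict[str, str] = {}
    tokens = [t.strip() for t in text.split(delimiter) if t.strip()]
    for pos, token in enumerate(tokens):
        if len(token) > 2 and token[1:3] == "__":
            rank = _RANK_PREFIXES.get(token[0].lower())
            name = token[3:]
        else:
            rank = RANK_ORDER[pos] if pos < len(RANK_ORDER) else None
            name = token
        if rank and name:
            ranks[rank] = name
    return ranks


def read_taxa_table(path: str | Path, rank_delimiter: str = ";") -> TaxaTable:
    """Read a taxa count TSV: ``taxon_id``, sample columns, ``lineage``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed TSV ({exc})") from exc
    if df.columns[0] != "taxon_id" or df.columns[-1] != "lineage":
        raise FormatError(
            f"{path}: first column must be 'taxon_id' and last column 'lineage'"
        )
    if df.shape[1] < 3:
        raise FormatError(f"{path}: no sample columns between taxon_id and lineage")
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or incomplete rows")

    taxa = df["taxon_id"].tolist()
    sample_cols = list(df.columns[1:-1])
    try:
        counts = df[sample_cols].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric count ({exc})") from exc
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValidationError(f"{path}: negative count")
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError(f"{path}: counts must be integers")
    matrix = pd.DataFrame(
        arr.T.astype(np.int64), index=sample_cols, columns=taxa
    )
    lineage = {
        taxon: parse_lineage(text, rank_delimiter)
        for taxon, text in zip(taxa, df["lineage"])
    }
    return TaxaTable(counts=matrix, lineage=lineage)


def write_taxa_table(table: TaxaTable, path: str | Path) -> None:
    """Write a :class:`TaxaTable` in the canonical TSV layout."""
    path = Path(path)
    rows = table.counts.T  # taxa x samples
    out = rows.copy()
    out.insert(0, "taxon_id", rows.index)
    prefix = {v: k for k, v in _RANK_PREFIXES.items() if k != "d"}
    lineage_col = []
    for taxon in rows.index:
        ranks = table.lineage.get(taxon, {})
        tokens = [
            f"{prefix[r]}__{ranks[r]}" for r in RANK_ORDER if r in ranks
        ]
        lineage_col.append(";".join(tokens) if tokens else f"p__{taxon}")
    out["lineage"] = lineage_col
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def summarize_groups(
    obs: pd.DataFrame,
    indicator: str,
    layer: str,
    treatments: tuple[Treatment, ...] = DEFAULT_TREATMENTS,
) -> list[GroupSummary]:
    """Per-treatment mean and sample SD for one (indicator, layer).

    Group order follows treatment application rate ascending, so the control
    comes first — the order agronomic tables print.
    """
    sub = obs[(obs["indicator"] == indicator) & (obs["layer"] == layer)]
    if sub.empty:
        raise ValidationError(f"no observations for ({indicator!r}, {layer!r})")
    order = [t.label for t in sorted(treatments, key=lambda t: t.rate)]
    present = [t for t in order if t in set(sub["treatment"])]
    extra = set(sub["treatment"]) - set(order)
    if extra:
        raise ValidationError(f"observations carry unknown treatment(s) {sorted(extra)}")
    summaries = []
    for label in present:
        vals = sub.loc[sub["treatment"] == label, "value"].to_numpy()
        if len(vals) < 2:
            raise InsufficientReplicationError(
                f"treatment {label!r} has {len(vals)} observation(s) "
                f"for ({indicator!r}, {layer!r}); need >= 2"
            )
        summaries.append(
            GroupSummary(
                group=label,
                n=len(vals),
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)),
            )
        )
    return summaries
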