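"""Readers and writers for models, media and essentiality annotations.

Three model dialects are supported:

* ``tsv-triplet`` -- this package's plain-text fixture dialect: a
  directory with ``reactions.tsv``, ``metabolites.tsv`` and
  ``genes.tsv``. Stoichiometry is encoded per reaction as
  ``met:coef;met:coef`` with negative coefficients for consumption.
* ``json`` -- BiGG-style model JSON (parsed directly).
* ``sbml-fbc`` -- SBML Level 3 with the FBC package, read through
  cobra/libsbml when available.

Media files are TSV with ``exchange_reaction_id`` and ``lower_bound``
columns; a long-format variant adds ``medium_label`` (and optionally
``is_salt`` / ``varied_element``) to hold a whole panel in one file.
Essentiality files are TSV with ``gene_id`` and ``status`` columns.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .gpr import parse_gpr
from .model import (
    ConfigurationError,
    EssentialityAnnotation,
    Metabolite,
    MetabolicModel,
    Medium,
    ModelError,
    Reaction,
)

_INF = 1e6  # default magnitude for unbounded fluxes in text formats


class ParseError(ValueError):
    """A model/media/annotation file failed to parse."""


# ---------------------------------------------------------------------------
# tsv-triplet dialect
# ---------------------------------------------------------------------------


def _encode_stoich(stoich: dict[str, float]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in sorted(stoich.items()))


def _decode_stoich(text: str, rxn_id: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            met, coef = part.rsplit(":", 1)
            out[met] = float(coef)
        except ValueError as exc:
            raise ParseError(
                f"reaction {rxn_id!r}: bad stoichiometry term {part!r}"
            ) from exc
    if not out:
        raise ParseError(f"reaction {rxn_id!r}: empty stoichiometry")
    return out


def read_model_tsv(path: str | Path) -> MetabolicModel:
    path = Path(path)
    rxn_file = path / "reactions.tsv"
    met_file = path / "metabolites.tsv"
    if not rxn_file.exists() or not met_file.exists():
        raise ParseError(f"{path} is not a tsv-triplet model directory")
    mets_df = pd.read_csv(met_file, sep="\t", dtype=str).fillna("")
    rxns_df = pd.read_csv(rxn_file, sep="\t", dtype=str).fillna("")
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", ""),
            compartment=row.get("compartment", ""),
            is_external=str(row.get("is_external", "")).lower() in ("1", "true", "yes"),
        )
        for _, row in mets_df.iterrows()
    ]
    reactions = []
    for _, row in rxns_df.iterrows():
        rid = row["id"]
        try:
            lb, ub = float(row["lower_bound"]), float(row["upper_bound"])
        except ValueError as exc:
            raise ParseError(f"reaction {rid!r}: non-numeric bounds") from exc
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=_decode_stoich(row["stoichiometry"], rid),
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(row.get("gpr", "")),
                subsystem=row.get("subsystem", ""),
                is_exchange=str(row.get("is_exchange", "")).lower() in ("1", "true", "yes"),
                is_biomass=str(row.get("is_biomass", "")).lower() in ("1", "true", "yes"),
                name=row.get("name", ""),
            )
        )
    try:
        return MetabolicModel(metabolites, reactions, id=path.name)
    except ModelError as exc:
        raise ParseError(f"invalid model at {path}: {exc}") from exc


def write_model_tsv(model: MetabolicModel, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "is_external": str(m.is_external).lower(),
            }
            for m in model.metabolites
        ]
    ).to_csv(path / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": _encode_stoich(r.stoichiometry),
                "lower_bound": f"{r.lower_bound:g}",
                "upper_bound": f"{r.upper_bound:g}",
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "is_exchange": str(r.is_exchange).lower(),
                "is_biomass": str(r.is_biomass).lower(),
            }
            for r in model.reactions
        ]
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame({"id": sorted(model.genes)}).to_csv(
        path / "genes.tsv", sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# BiGG-style JSON
# ---------------------------------------------------------------------------


def read_model_json(path: str | Path) -> MetabolicModel:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path} is not valid JSON: {exc}") from exc
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
            )
            for m in data["metabolites"]
        ]
        reactions = []
        for r in data["reactions"]:
            stoich = {m: float(c) for m, c in r["metabolites"].items()}
            objective = float(r.get("objective_coefficient", 0.0))
            rid = r["id"]
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=float(r.get("lower_bound", -_INF)),
                    upper_bound=float(r.get("upper_bound", _INF)),
                    gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                    subsystem=r.get("subsystem", "") or "",
                    is_exchange=len(stoich) == 1 and not objective,
                    is_biomass=objective != 0.0 or "biomass" in rid.lower(),
                    name=r.get("name", ""),
                )
            )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing/invalid element {exc}") from exc
    n_biomass = sum(r.is_biomass for r in reactions)
    if n_biomass > 1:
        # keep only the objective-bearing reaction as biomass
        reactions = [
            r
            if not r.is_biomass
            else Reaction(
                id=r.id,
                stoichiometry=r.stoichiometry,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=r.gpr,
                subsystem=r.subsystem,
                is_exchange=r.is_exchange,
                is_biomass=float(
                    next(
                        x.get("objective_coefficient", 0.0)
                        for x in data["reactions"]
                        if x["id"] == r.id
                    )
                )
                != 0.0,
                name=r.name,
            )
            for r in reactions
        ]
    try:
        return MetabolicModel(metabolites, reactions, id=data.get("id", path.stem))
    except ModelError as exc:
        raise ParseError(f"invalid model in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# SBML-FBC via cobra
# ---------------------------------------------------------------------------


def read_model_sbml(path: str | Path) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ParseError(
            "SBML support requires the 'cobra' optional dependency"
        ) from exc
    cm = cobra.io.read_sbml_model(str(path))
    return from_cobra(cm)


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobra.Model into the internal representation."""
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cm.metabolites
    ]
    objective_ids = {
        r.id for r in cm.reactions if getattr(r, "objective_coefficient", 0.0)
    }
    reactions = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
                subsystem=r.subsystem or "",
                is_exchange=len(stoich) == 1 and r.id not in objective_ids,
                is_biomass=r.id in objective_ids,
                name=r.name or "",
            )
        )
    return MetabolicModel(metabolites, reactions, id=cm.id or "cobra_model")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_READERS = {
    "tsv-triplet": read_model_tsv,
    "json": read_model_json,
    "sbml-fbc": read_model_sbml,
}


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model, inferring the dialect from the path if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "tsv-triplet"
        elif path.suffix == ".json":
            format = "json"
        else:
            format = "sbml-fbc"
    try:
        reader = _READERS[format]
    except KeyError:
        raise ConfigurationError(
            f"unknown model format {format!r}; expected one of {sorted(_READERS)}"
        ) from None
    return reader(path)


# ---------------------------------------------------------------------------
# media and annotations
# ---------------------------------------------------------------------------


def read_medium(path: str | Path, label: str | None = None) -> Medium:
    df = pd.read_csv(path, sep="\t")
    if not {"exchange_reaction_id", "lower_bound"} <= set(df.columns):
        raise ParseError(
            f"{path}: medium file needs exchange_reaction_id and lower_bound columns"
        )
    bounds = dict(zip(df["exchange_reaction_id"], df["lower_bound"].astype(float)))
    return Medium(bounds, label=label or Path(path).stem)


def write_medium(medium: Medium, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "exchange_reaction_id": sorted(medium.uptake_bounds),
            "lower_bound": [medium.uptake_bounds[k] for k in sorted(medium.uptake_bounds)],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_media_panel(path: str | Path) -> list[Medium]:
    """Long-format panel TSV with a medium_label column -> list of media."""
    df = pd.read_csv(path, sep="\t")
    needed = {"medium_label", "exchange_reaction_id", "lower_bound"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: panel file needs columns {sorted(needed)}")
    media = []
    for label, grp in df.groupby("medium_label", sort=True):
        bounds = dict(zip(grp["exchange_reaction_id"], grp["lower_bound"].astype(float)))
        media.append(Medium(bounds, label=str(label)))
    return media


def write_media_panel(media: list[Medium], path: str | Path) -> Path:
    rows = []
    for medium in media:
        for ex in sorted(medium.uptake_bounds):
            rows.append(
                {
                    "medium_label": medium.label,
                    "exchange_reaction_id": ex,
                    "lower_bound": medium.uptake_bounds[ex],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_essentiality(
    path: str | Path, unknown_policy: str = "nonessential"
) -> EssentialityAnnotation:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "status"} <= set(df.columns):
        raise ParseError(f"{path}: essentiality file needs gene_id and status columns")
    mapping = dict(zip(df["gene_id"].astype(str), df["status"].astype(str)))
    try:
        return EssentialityAnnotation(
            mapping, source=str(path), unknown_policy=unknown_policy
        )
    except ConfigurationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
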