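"""Model, dataset and SBML input/output.

Three text formats are supported: a declarative YAML model file that
round-trips the full network (species, reactions, rate laws, parameters,
bounds, variant settings) losslessly; SBML Level 3 Version 2 export/import
of any variant, with kinetic laws emitted as MathML; and comma-separated
measurement tables (UTF-8, header row, '.' decimal) shared by the synthetic
generator and the estimation reader.
"""

from __future__ import annotations

import io as _io
import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .network import (
    DEFAULT_VARIANT_SETTINGS,
    ModelVariant,
    ParameterSet,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    build_reference_network,
)

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_model",
    "load_model",
    "export_sbml",
    "import_sbml",
    "network_diff",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "write_manifest",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


# ---------------------------------------------------------------------------
# Declarative model file
# ---------------------------------------------------------------------------

def network_to_dict(
    network: ReactionNetwork,
    variants: Mapping[str, Mapping] | None = None,
) -> dict:
    return {
        "species": [
            {
                "id": s.id,
                "display_name": s.display_name,
                "initial_concentration": float(s.initial_concentration),
                "is_dynamic": bool(s.is_dynamic),
            }
            for s in network.species
        ],
        "reactions": [
            {
                "step": r.step_index,
                "name": r.name,
                "law": r.law.value,
                "reactants": dict(r.reactants),
                "products": dict(r.products),
                "modifier": r.modifier,
                "parameters": dict(r.parameters),
            }
            for r in network.reactions
        ],
        "parameters": {k: float(v) for k, v in network.parameters.values.items()},
        "bounds": {
            k: [float(lo), float(hi)]
            for k, (lo, hi) in network.parameters.bounds.items()
        },
        "variants": {
            k: dict(v) for k, v in (variants or DEFAULT_VARIANT_SETTINGS).items()
        },
    }


def network_from_dict(doc: Mapping) -> tuple[ReactionNetwork, dict]:
    species = [
        Species(
            d["id"],
            d.get("display_name", ""),
            float(d.get("initial_concentration", 0.0)),
            bool(d.get("is_dynamic", True)),
        )
        for d in doc["species"]
    ]
    reactions = [
        Reaction(
            step_index=int(d["step"]),
            reactants={k: int(v) for k, v in d["reactants"].items()},
            products={k: int(v) for k, v in d["products"].items()},
            law=RateLaw(d["law"]),
            parameters=dict(d["parameters"]),
            modifier=d.get("modifier"),
            name=d.get("name", ""),
        )
        for d in doc["reactions"]
    ]
    params = ParameterSet(
        {k: float(v) for k, v in doc["parameters"].items()},
        {k: (float(lo), float(hi)) for k, (lo, hi) in doc.get("bounds", {}).items()},
    )
    variants = {k: dict(v) for k, v in doc.get("variants", {}).items()}
    return ReactionNetwork(species, reactions, params), variants


def save_model(
    path: str | Path,
    network: ReactionNetwork,
    variants: Mapping[str, Mapping] | None = None,
) -> None:
    doc = network_to_dict(network, variants)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_model(path: str | Path) -> tuple[ReactionNetwork, dict]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return network_from_dict(doc)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _mathml_ci(parent: etree._Element, name: str) -> None:
    ci = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
    ci.text = f" {name} "


def _mathml_apply(parent: etree._Element, op: str) -> etree._Element:
    ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(ap, f"{{{MATHML_NS}}}{op}")
    return ap


def _kinetic_law_math(reaction: Reaction) -> etree._Element:
    math = etree.Element(f"{{{MATHML_NS}}}math")
    if reaction.law is RateLaw.MICHAELIS_MENTEN:
        (substrate,) = reaction.reactants
        div = _mathml_apply(math, "divide")
        num = _mathml_apply(div, "times")
        if "kcat" in reaction.parameters:
            _mathml_ci(num, reaction.parameters["kcat"])
            _mathml_ci(num, reaction.modifier)
        else:
            _mathml_ci(num, reaction.parameters["V"])
        _mathml_ci(num, substrate)
        den = _mathml_apply(div, "plus")
        _mathml_ci(den, reaction.parameters["Km"])
        _mathml_ci(den, substrate)
        return math

    def product_term(parent, k_name, species_counts, extra=None):
        factors = [k_name]
        if extra:
            factors.append(extra)
        for sid, nu in species_counts.items():
            factors.extend([sid] * nu)
        if len(factors) == 1:
            _mathml_ci(parent, factors[0])
        else:
            times = _mathml_apply(parent, "times")
            for f in factors:
                _mathml_ci(times, f)

    if "kr" in reaction.parameters:
        minus = _mathml_apply(math, "minus")
        product_term(
            minus, reaction.parameters["kf"], reaction.reactants,
            extra=reaction.modifier,
        )
        product_term(minus, reaction.parameters["kr"], reaction.products)
    else:
        product_term(
            math, reaction.parameters["kf"], reaction.reactants,
            extra=reaction.modifier,
        )
    return math


def export_sbml(variant: ModelVariant, path: str | Path | None = None) -> bytes:
    """Serialize a variant (network + effective parameters/initials) as
    SBML Level 3 Version 2.

    The EGF bath and the constant phosphatases are boundary-condition
    species; kinetic laws are written as explicit MathML so any
    SBML-compliant tool reproduces the same rate expressions.
    """
    net = variant.network
    params = variant.effective_parameters()
    initials = variant.effective_initials()
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", f"egfr_erk_{variant.name}")
    model.set("name", f"EGFR-ERK signaling, {variant.name} variant")
    loc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(loc, f"{{{SBML_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")
    comp.set("spatialDimensions", "3")
    los = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    boundary = {s.id for s in net.species if not s.is_dynamic} | {"EGF"}
    for s in net.species:
        el = etree.SubElement(los, f"{{{SBML_NS}}}species")
        el.set("id", s.id)
        el.set("name", s.display_name)
        el.set("compartment", "cell")
        el.set("initialConcentration", repr(float(initials[s.id])))
        el.set("boundaryCondition", "true" if s.id in boundary else "false")
        el.set("constant", "false")
        el.set("hasOnlySubstanceUnits", "false")
    lop = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name in sorted(params.values):
        el = etree.SubElement(lop, f"{{{SBML_NS}}}parameter")
        el.set("id", name)
        el.set("value", repr(float(params[name])))
        el.set("constant", "true")
    lor = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in net.reactions:
        el = etree.SubElement(lor, f"{{{SBML_NS}}}reaction")
        el.set("id", f"step_{r.step_index}")
        el.set("name", r.name or f"step {r.step_index}")
        el.set("reversible", str("kr" in r.parameters).lower())
        if r.reactants:
            lr = etree.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for sid, nu in r.reactants.items():
                sr = etree.SubElement(lr, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", sid)
                sr.set("stoichiometry", str(nu))
                sr.set("constant", "true")
        if r.products:
            lp = etree.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for sid, nu in r.products.items():
                sr = etree.SubElement(lp, f"{{{SBML_NS}}}speciesReference")
                sr.set("species", sid)
                sr.set("stoichiometry", str(nu))
                sr.set("constant", "true")
        if r.modifier is not None:
            lm = etree.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
            mr = etree.SubElement(lm, f"{{{SBML_NS}}}modifierSpeciesReference")
            mr.set("species", r.modifier)
        kl = etree.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_kinetic_law_math(r))
    payload = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if path is not None:
        Path(path).write_bytes(payload)
    return payload


class SBMLImportError(ValueError):
    def __init__(self, message: str, path_hint: str = "") -> None:
        super().__init__(f"{message}" + (f" (at {path_hint})" if path_hint else ""))


def _parse_mathml(math: etree._Element) -> list:
    """MathML apply-tree -> nested [op, args...] with ci leaves as strings."""

    def walk(el):
        tag = etree.QName(el).localname
        if tag == "math":
            children = [c for c in el if isinstance(c.tag, str)]
            if len(children) != 1:
                raise SBMLImportError("math element must have one child")
            return walk(children[0])
        if tag == "ci":
            return el.text.strip()
        if tag == "cn":
            return float(el.text.strip())
        if tag == "apply":
            children = [c for c in el if isinstance(c.tag, str)]
            op = etree.QName(children[0]).localname
            return [op] + [walk(c) for c in children[1:]]
        raise SBMLImportError(f"unsupported MathML element <{tag}>")

    return walk(math)


def _law_from_math(
    tree, reactants: dict, products: dict, modifier: str | None, step: int
) -> tuple[RateLaw, dict[str, str]]:
    """Recognize the package's two rate-law shapes in a parsed MathML tree."""

    def flat_product(node) -> list[str]:
        if isinstance(node, str):
            return [node]
        if isinstance(node, list) and node[0] == "times":
            out = []
            for a in node[1:]:
                out.extend(flat_product(a))
            return out
        raise SBMLImportError(f"step {step}: expected a product term")

    species = set(reactants) | set(products) | ({modifier} if modifier else set())

    if isinstance(tree, list) and tree[0] == "divide":
        num = flat_product(tree[1])
        den = tree[2]
        if not (isinstance(den, list) and den[0] == "plus" and len(den) == 3):
            raise SBMLImportError(f"step {step}: malformed MM denominator")
        km_name = den[1]
        non_species = [n for n in num if n not in species]
        if len(non_species) != 1:
            raise SBMLImportError(f"step {step}: malformed MM numerator")
        rate_const = non_species[0]
        role = "kcat" if modifier is not None and modifier in num else "V"
        return RateLaw.MICHAELIS_MENTEN, {role: rate_const, "Km": km_name}
    if isinstance(tree, list) and tree[0] == "minus" and len(tree) == 3:
        fwd = [n for n in flat_product(tree[1]) if n not in species]
        rev = [n for n in flat_product(tree[2]) if n not in species]
        if len(fwd) != 1 or len(rev) != 1:
            raise SBMLImportError(f"step {step}: malformed mass-action law")
        return RateLaw.MASS_ACTION_REVERSIBLE, {"kf": fwd[0], "kr": rev[0]}
    fwd = [n for n in flat_product(tree) if n not in species]
    if len(fwd) != 1:
        raise SBMLImportError(f"step {step}: malformed mass-action law")
    return RateLaw.MASS_ACTION_IRREVERSIBLE, {"kf": fwd[0]}


def import_sbml(source: str | Path | bytes) -> ReactionNetwork:
    """Rebuild a :class:`ReactionNetwork` from an SBML document.

    Supports the rate-law vocabulary of this model family: mass action
    (optionally reversible, optionally with a forward-rate modifier) and
    Michaelis-Menten with an explicit Vmax or a kcat * modifier numerator.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(str(source)).getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise SBMLImportError("no <model> element")
    species = []
    for el in model.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        sid = el.get("id")
        boundary = el.get("boundaryCondition") == "true"
        species.append(
            Species(
                sid,
                el.get("name", sid),
                float(el.get("initialConcentration", "0")),
                # the EGF bath keeps a (trivially constant) ODE slot
                is_dynamic=(sid == "EGF") or not boundary,
            )
        )
    values = {}
    for el in model.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        values[el.get("id")] = float(el.get("value"))
    reactions = []
    for el in model.findall(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = el.get("id", "")
        try:
            step = int(rid.rsplit("_", 1)[-1])
        except ValueError as exc:
            raise SBMLImportError(f"reaction id {rid!r} lacks a step index") from exc
        reactants = {
            sr.get("species"): int(float(sr.get("stoichiometry", "1")))
            for sr in el.findall(
                f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
            )
        }
        products = {
            sr.get("species"): int(float(sr.get("stoichiometry", "1")))
            for sr in el.findall(
                f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
            )
        }
        modifiers = [
            mr.get("species")
            for mr in el.findall(
                f"{{{SBML_NS}}}listOfModifiers/{{{SBML_NS}}}modifierSpeciesReference"
            )
        ]
        modifier = modifiers[0] if modifiers else None
        math = el.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            raise SBMLImportError(f"reaction {rid!r} has no kinetic law")
        tree = _parse_mathml(math)
        law, roles = _law_from_math(tree, reactants, products, modifier, step)
        reactions.append(
            Reaction(
                step_index=step,
                reactants=reactants,
                products=products,
                law=law,
                parameters=roles,
                modifier=modifier,
                name=el.get("name", ""),
            )
        )
    return ReactionNetwork(species, reactions, ParameterSet(values))


def network_diff(a: ReactionNetwork, b: ReactionNetwork) -> list[str]:
    """Structural differences between two networks, one message per line.

    Used to audit an imported SBML document against the built-in reference.
    An empty list means structurally identical (parameter values are
    compared, too)."""
    out: list[str] = []
    sa, sb = set(a.species_ids), set(b.species_ids)
    for sid in sorted(sa - sb):
        out.append(f"species {sid!r} only in first")
    for sid in sorted(sb - sa):
        out.append(f"species {sid!r} only in second")
    ra = {r.step_index: r for r in a.reactions}
    rb = {r.step_index: r for r in b.reactions}
    for step in sorted(set(ra) | set(rb)):
        x, y = ra.get(step), rb.get(step)
        if x is None or y is None:
            out.append(f"step {step} present in only one network")
            continue
        if x.law is not y.law:
            out.append(f"step {step}: law {x.law.value} vs {y.law.value}")
        if dict(x.reactants) != dict(y.reactants) or dict(x.products) != dict(
            y.products
        ):
            out.append(f"step {step}: stoichiometry differs")
        if x.modifier != y.modifier:
            out.append(f"step {step}: modifier {x.modifier!r} vs {y.modifier!r}")
    for name in sorted(set(a.parameters.values) | set(b.parameters.values)):
        va = a.parameters.values.get(name)
        vb = b.parameters.values.get(name)
        if va is None or vb is None:
            out.append(f"parameter {name!r} present in only one network")
        elif not np.isclose(va, vb, rtol=1e-12, atol=0.0):
            out.append(f"parameter {name!r}: {va} vs {vb}")
    return out


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

class DatasetFormatError(ValueError):
    """Malformed measurement table; messages carry 1-based line numbers
    (line 1 is the header)."""


_KEY_COLUMNS = ["cell_line", "protein", "dose", "time", "replicate"]
_REPLICATE_SCHEMA = _KEY_COLUMNS + ["raw_value", "normalized_value"]
_COMPACT_SCHEMA = ["cell_line", "protein", "dose", "time", "value"]


def write_dataset(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement table (see module docstring).

    Accepts the replicate-level schema written by the synthetic generator or
    the compact normalized schema consumed by the estimation objective.
    Malformed content raises :class:`DatasetFormatError` with the offending
    line number.
    """
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise DatasetFormatError(f"unreadable CSV: {exc}") from exc
    cols = list(table.columns)
    if set(_REPLICATE_SCHEMA) <= set(cols):
        value_cols = ["raw_value", "normalized_value"]
        key_cols = _KEY_COLUMNS
    elif set(_COMPACT_SCHEMA) <= set(cols):
        value_cols = ["value"]
        key_cols = ["cell_line", "protein", "dose", "time"]
    else:
        raise DatasetFormatError(
            f"missing columns: expected {_REPLICATE_SCHEMA} or "
            f"{_COMPACT_SCHEMA}, found {cols}"
        )
    numeric_cols = [c for c in key_cols if c not in ("cell_line", "protein")]
    numeric_cols += value_cols
    out = table.copy()
    for col in numeric_cols:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed)
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2
            raise DatasetFormatError(
                f"line {line}: non-numeric {col} value {out[col].iloc[line - 2]!r}"
            )
        out[col] = parsed
    for col in ("dose", "time", *value_cols):
        neg = out[col] < 0
        if neg.any():
            line = int(np.argmax(neg.to_numpy())) + 2
            raise DatasetFormatError(
                f"line {line}: negative {col} value {out[col].iloc[line - 2]}"
            )
    dup = out.duplicated(subset=key_cols)
    if dup.any():
        line = int(np.argmax(dup.to_numpy())) + 2
        raise DatasetFormatError(f"line {line}: duplicated key {key_cols}")
    return out


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, config: Mapping, seed: int | None) -> None:
    """Reproducibility record written next to every CLI output."""
    from . import __version__

    doc = {
        "package": "egfr-erk",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": {k: _jsonable(v) for k, v in config.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True), encoding="utf-8")


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    if isinstance(v, Mapping):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, Path):
        return str(v)
    return v
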