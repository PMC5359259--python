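"""Model-variant ledger: constraint sets reducing the full kinetic model.

The full conjugation model carries 19 kinetic parameters: for each of the
three subpopulations a maximal growth rate, lag half-time, lag Hill
coefficient, growth Monod constant and resource-depletion coefficient, plus
a maximal transfer rate and transfer Monod constant for each plasmid-bearing
population.  A :class:`VariantSpec` is an ordered list of constraints —
``share`` (collapse a parameter group to one free value), ``fix`` (pin to a
constant) and ``drop`` (replace a functional term by its limiting form) —
that maps the full structure to a reduced free-parameter vector.  The
sixteen named variants V0–V15 ship in ``data/variants.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .model import (
    LAG_HILL,
    LAG_NONE,
    RES_LINEAR,
    RES_MONOD,
    RES_NONE,
    DONOR_LIKE,
    POPULATIONS,
    GeneralParameters,
    GrowthKinetics,
    TransferKinetics,
)

#: canonical ordering of the 19 kinetic parameter slots of the full model
SLOTS = tuple(
    [f"psi_max_{p}" for p in POPULATIONS]
    + [f"K_L_{p}" for p in POPULATIONS]
    + [f"n_{p}" for p in POPULATIONS]
    + [f"K_G_{p}" for p in POPULATIONS]
    + [f"e_{p}" for p in POPULATIONS]
    + [f"gamma_max_{j}" for j in DONOR_LIKE]
    + [f"K_T_{j}" for j in DONOR_LIKE]
)

_DROP_TERMS = ("growth_monod", "growth_resource", "lag", "transfer_monod",
               "transfer_resource", "depletion")


@dataclass(frozen=True)
class VariantSpec:
    """A named reduction of the full model to a free-parameter vector."""

    name: str
    constraints: tuple
    description: str = ""
    free_order: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "_resolution", _resolve_structure(self))

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the free kinetic parameters, in free-vector order."""
        return self._resolution["free_names"]

    @property
    def n_kinetic(self) -> int:
        """Number of free kinetic parameters after applying all constraints."""
        return len(self.free_names)

    def resolve(self, free_vector) -> GeneralParameters:
        """Expand a free-parameter vector to the full kinetic structure."""
        return resolve_variant(self, free_vector)

    def free_vector_from(self, values: dict[str, float]):
        """Order a {name: value} mapping into this variant's free vector."""
        missing = set(self.free_names) - set(values)
        if missing:
            raise KeyError(f"missing free parameters: {sorted(missing)}")
        return [values[name] for name in self.free_names]


def _flatten(constraints):
    out = []
    for c in constraints:
        if isinstance(c, list):
            out.extend(_flatten(c))
        else:
            out.append(c)
    return out


def _resolve_structure(variant: VariantSpec) -> dict:
    """Apply the constraint list to the slot ledger.

    Returns the per-slot disposition (free / shared-as / fixed value /
    removed) and the functional forms selected for every rate law.
    """
    display = {s: s for s in SLOTS}      # slot -> free-parameter name
    fixed: dict[str, float] = {}
    removed: set[str] = set()
    lag_form = {p: LAG_HILL for p in POPULATIONS}
    growth_res = {p: RES_MONOD for p in POPULATIONS}
    transfer_res = {j: RES_MONOD for j in DONOR_LIKE}
    depleted = {p: True for p in POPULATIONS}

    def _remove(slot):
        removed.add(slot)
        display.pop(slot, None)

    for con in _flatten(list(variant.constraints)):
        if len(con) != 1:
            raise ValueError(f"malformed constraint: {con!r}")
        kind, payload = next(iter(con.items()))
        if kind == "fix":
            params = payload.get("params") or [payload["param"]]
            for slot in params:
                _check_slot(slot)
                fixed[slot] = float(payload["value"])
                display.pop(slot, None)
        elif kind == "share":
            group = payload["params"]
            for slot in group:
                _check_slot(slot)
                if slot not in display:
                    raise ValueError(
                        f"{variant.name}: cannot share non-free slot {slot}")
                display[slot] = payload["as"]
        elif kind == "drop":
            term = payload["term"]
            if term not in _DROP_TERMS:
                raise ValueError(f"unknown drop term {term!r}")
            for pop in payload["pops"]:
                if term == "growth_monod":
                    growth_res[pop] = RES_LINEAR
                    _remove(f"K_G_{pop}")
                elif term == "growth_resource":
                    growth_res[pop] = RES_NONE
                    _remove(f"K_G_{pop}")
                elif term == "lag":
                    lag_form[pop] = LAG_NONE
                    _remove(f"K_L_{pop}")
                    _remove(f"n_{pop}")
                elif term == "transfer_monod":
                    transfer_res[pop] = RES_LINEAR
                    _remove(f"K_T_{pop}")
                elif term == "transfer_resource":
                    transfer_res[pop] = RES_NONE
                    _remove(f"K_T_{pop}")
                elif term == "depletion":
                    depleted[pop] = False
                    _remove(f"e_{pop}")
        else:
            raise ValueError(f"unknown constraint kind {kind!r}")

    free_names: list[str] = []
    for slot in SLOTS:
        if slot in display and display[slot] not in free_names:
            free_names.append(display[slot])
    if variant.free_order is not None:
        if sorted(variant.free_order) != sorted(free_names):
            raise ValueError(
                f"{variant.name}: free_order {variant.free_order} does not "
                f"match derived free names {free_names}")
        free_names = list(variant.free_order)

    return {
        "display": display,
        "fixed": fixed,
        "removed": removed,
        "lag_form": lag_form,
        "growth_res": growth_res,
        "transfer_res": transfer_res,
        "depleted": depleted,
        "free_names": tuple(free_names),
    }


def _check_slot(slot):
    if slot not in SLOTS:
        raise ValueError(f"unknown parameter slot {slot!r}")


def resolve_variant(variant: VariantSpec, free_vector) -> GeneralParameters:
    """Expand a variant's free-parameter vector to :class:`GeneralParameters`.

    Shared slots are duplicated, fixed slots pinned, and dropped terms
    encoded as their limiting functional forms on the kinetics objects.
    """
    res = variant._resolution
    names = res["free_names"]
    free_vector = list(free_vector)
    if len(free_vector) != len(names):
        raise ValueError(
            f"{variant.name} expects {len(names)} free parameters "
            f"({', '.join(names)}); got {len(free_vector)}")
    values = dict(zip(names, free_vector))

    def slot_value(slot, default=0.0):
        if slot in res["fixed"]:
            return res["fixed"][slot]
        if slot in res["display"]:
            return values[res["display"][slot]]
        return default

    growth = {}
    for pop in POPULATIONS:
        growth[pop] = GrowthKinetics(
            psi_max=slot_value(f"psi_max_{pop}"),
            K_L=slot_value(f"K_L_{pop}"),
            n=slot_value(f"n_{pop}", default=1.0),
            K_G=slot_value(f"K_G_{pop}"),
            e=slot_value(f"e_{pop}") if res["depleted"][pop] else None,
            lag_form=res["lag_form"][pop],
            resource_form=res["growth_res"][pop],
        )
    transfer = {}
    for j in DONOR_LIKE:
        transfer[j] = TransferKinetics(
            gamma_max=slot_value(f"gamma_max_{j}"),
            K_T=slot_value(f"K_T_{j}"),
            resource_form=res["transfer_res"][j],
        )
    return GeneralParameters(growth=growth, transfer=transfer)


def _spec_from_dict(entry: dict) -> VariantSpec:
    return VariantSpec(
        name=entry["name"],
        # nested lists (YAML aliases of other variants' lists) stay intact;
        # _flatten handles them at resolution time
        constraints=tuple(entry.get("constraints", [])),
        description=entry.get("description", "").strip(),
        free_order=tuple(entry["free_order"]) if "free_order" in entry else None,
    )


@lru_cache(maxsize=None)
def load_variants(path: str | None = None) -> dict[str, VariantSpec]:
    """Load the variant ledger from YAML (packaged default: V0–V15)."""
    if path is None:
        text = (resources.files("matefit") / "data" / "variants.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    specs = {}
    for entry in doc["variants"]:
        spec = _spec_from_dict(entry)
        specs[spec.name] = spec
    return specs


def get_variant(name: str) -> VariantSpec:
    """Look up a named variant (V0–V15) from the packaged ledger."""
    variants = load_variants()
    try:
        return variants[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; available: {sorted(variants)}") from None
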