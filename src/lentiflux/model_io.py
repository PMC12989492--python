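"""Genome-scale metabolic model containers and I/O.

The on-disk primary dialect is the BiGG-JSON schema subset (``metabolites``,
``reactions`` with ``metabolites``/``lower_bound``/``upper_bound``/
``gene_reaction_rule``/``subsystem``).  SBML Level 3 + FBC files are read
best-effort through COBRApy when it is installed.  Gene-protein-reaction
(GPR) rules are parsed into explicit boolean trees so that downstream code
can evaluate them with AND -> min / OR -> sum semantics.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import sparse

__all__ = [
    "GprParseError",
    "ModelValidationError",
    "ToyModelError",
    "GprRule",
    "EMPTY_GPR",
    "parse_gpr",
    "Reaction",
    "MetabolicModel",
    "read_model_json",
    "write_model_json",
    "read_model_sbml",
    "validate_model",
    "SentinelSpec",
    "ToyModelSpec",
    "DEFAULT_SENTINELS",
    "build_toy_model",
]


class GprParseError(ValueError):
    """A gene-reaction rule string could not be parsed."""


class ModelValidationError(ValueError):
    """A model file violates the schema or a model invariant."""


class ToyModelError(ValueError):
    """A toy-model specification cannot produce a feasible model."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_VALID_KINDS = frozenset({"empty", "gene", "all", "any"})


@dataclass(frozen=True)
class GprRule:
    """Boolean expression tree over gene identifiers.

    ``kind`` is one of ``"empty"`` (no gene association — a distinct
    sentinel, not an empty OR), ``"gene"`` (leaf), ``"all"`` (logical and)
    or ``"any"`` (logical or).
    """

    kind: str
    gene: str | None = None
    children: tuple["GprRule", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")
        if self.kind == "gene" and not self.gene:
            raise ValueError("gene leaf requires a non-empty gene id")
        if self.kind in ("all", "any") and len(self.children) < 2:
            raise ValueError(f"{self.kind!r} node requires at least two children")
        if self.kind in ("empty", "gene") and self.children:
            raise ValueError(f"{self.kind!r} node cannot have children")

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def genes(self) -> frozenset[str]:
        """Set of gene ids referenced anywhere in the tree."""
        if self.kind == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def to_string(self) -> str:
        """Canonical rule string (``and`` binds tighter than ``or``)."""
        if self.kind == "empty":
            return ""
        if self.kind == "gene":
            return self.gene  # type: ignore[return-value]
        if self.kind == "all":
            parts = [
                f"({c.to_string()})" if c.kind in ("any", "all") else c.to_string()
                for c in self.children
            ]
            return " and ".join(parts)
        parts = [
            f"({c.to_string()})" if c.kind == "any" else c.to_string()
            for c in self.children
        ]
        return " or ".join(parts)


EMPTY_GPR = GprRule("empty")

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule_text: str | None) -> GprRule:
    """Parse a BiGG-style rule string into a :class:`GprRule` tree.

    ``and``/``or`` are case-insensitive, ``and`` binds tighter than ``or``,
    and gene tokens are any non-whitespace runs excluding parentheses.  An
    empty or whitespace-only string yields the empty-rule sentinel.
    """
    if rule_text is None or not rule_text.strip():
        return EMPTY_GPR
    tokens = [(m.group(), m.start()) for m in _GPR_TOKEN.finditer(rule_text)]
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprRule:
        terms = [parse_and()]
        while True:
            nxt = peek()
            if nxt is None or nxt[0].lower() != "or":
                break
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprRule("any", children=tuple(terms))

    def parse_and() -> GprRule:
        factors = [parse_atom()]
        while True:
            nxt = peek()
            if nxt is None or nxt[0].lower() != "and":
                break
            advance()
            factors.append(parse_atom())
        return (
            factors[0]
            if len(factors) == 1
            else GprRule("all", children=tuple(factors))
        )

    def parse_atom() -> GprRule:
        nxt = peek()
        if nxt is None:
            raise GprParseError(
                f"unexpected end of rule at position {len(rule_text)}: {rule_text!r}"
            )
        tok, at = advance()
        if tok == "(":
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GprParseError(
                    f"unbalanced parenthesis opened at position {at}: {rule_text!r}"
                )
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(
                f"unexpected token {tok!r} at position {at}: {rule_text!r}"
            )
        return GprRule("gene", gene=tok)

    node = parse_or()
    if pos < len(tokens):
        tok, at = tokens[pos]
        raise GprParseError(f"unexpected token {tok!r} at position {at}: {rule_text!r}")
    return node


# ---------------------------------------------------------------------------
# Reactions and models
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds, subsystem and GPR."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    gpr: GprRule = EMPTY_GPR

    @property
    def is_exchange(self) -> bool:
        """True for single-metabolite boundary stubs (exchanges/demands)."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """Ordered metabolite/reaction collection with an implicit S matrix."""

    metabolites: list[str]
    reactions: list[Reaction]
    id: str = "model"

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return frozenset(out)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Sparse S (metabolites x reactions), consistent with stoichiometries."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.stoichiometry.items():
                rows.append(met_idx[met])
                cols.append(j)
                vals.append(float(coeff))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )


def validate_model(model: MetabolicModel) -> list[str]:
    """Return a list of invariant violations (empty list means valid).

    Checks id uniqueness, stoichiometry/metabolite consistency, bound
    ordering, and that every non-exchange reaction is mass-connected (each
    of its metabolites is shared with at least one other reaction).
    """
    violations: list[str] = []
    seen_m: set[str] = set()
    for m in model.metabolites:
        if m in seen_m:
            violations.append(f"duplicate metabolite id {m!r}")
        seen_m.add(m)
    seen_r: set[str] = set()
    met_usage: dict[str, int] = {m: 0 for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.id in seen_r:
            violations.append(f"duplicate reaction id {rxn.id!r}")
        seen_r.add(rxn.id)
        if not rxn.stoichiometry:
            violations.append(f"reaction {rxn.id!r} has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(
                f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} exceeds "
                f"upper_bound {rxn.upper_bound}"
            )
        for met in rxn.stoichiometry:
            if met not in met_usage:
                violations.append(
                    f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                )
            else:
                met_usage[met] += 1
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        for met in rxn.stoichiometry:
            if met_usage.get(met, 0) < 2:
                violations.append(
                    f"reaction {rxn.id!r}: metabolite {met!r} is a dead end"
                )
    return violations


# ---------------------------------------------------------------------------
# BiGG-JSON I/O
# ---------------------------------------------------------------------------


def _record_bounds(rec: Mapping, rid: str) -> tuple[float, float]:
    lb = rec.get("lower_bound")
    ub = rec.get("upper_bound")
    if lb is None and ub is None:
        # COBRA convention when a file omits bounds.
        if rec.get("reversibility"):
            return -1000.0, 1000.0
        return 0.0, 1000.0
    if lb is None:
        lb = -1000.0 if rec.get("reversibility") else 0.0
    if ub is None:
        ub = 1000.0
    lb, ub = float(lb), float(ub)
    if lb > ub:
        raise ModelValidationError(
            f"reaction {rid!r}: lower_bound {lb} exceeds upper_bound {ub}"
        )
    return lb, ub


def read_model_json(path: str | Path) -> MetabolicModel:
    """Read and validate a BiGG-JSON model file."""
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict) or "reactions" not in data:
        raise ModelValidationError(f"{path}: missing 'reactions' section")

    metabolites: list[str] = []
    for i, rec in enumerate(data.get("metabolites", [])):
        mid = rec.get("id") if isinstance(rec, dict) else rec
        if not mid:
            raise ModelValidationError(f"{path}: metabolite record {i} lacks an id")
        if mid in metabolites:
            raise ModelValidationError(f"{path}: duplicate metabolite id {mid!r}")
        metabolites.append(mid)
    met_set = set(metabolites)

    reactions: list[Reaction] = []
    seen: set[str] = set()
    for i, rec in enumerate(data["reactions"]):
        rid = rec.get("id")
        if not rid:
            raise ModelValidationError(f"{path}: reaction record {i} lacks an id")
        if rid in seen:
            raise ModelValidationError(f"{path}: duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich_raw = rec.get("metabolites")
        if not stoich_raw:
            raise ModelValidationError(
                f"{path}: reaction {rid!r} lacks a 'metabolites' stoichiometry"
            )
        stoich: dict[str, float] = {}
        for met, coeff in stoich_raw.items():
            if met not in met_set:
                raise ModelValidationError(
                    f"{path}: reaction {rid!r} references undeclared metabolite {met!r}"
                )
            stoich[met] = float(coeff)
        lb, ub = _record_bounds(rec, rid)
        try:
            gpr = parse_gpr(rec.get("gene_reaction_rule", ""))
        except GprParseError as exc:
            raise ModelValidationError(
                f"{path}: reaction {rid!r} has a malformed GPR rule: {exc}"
            ) from exc
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=rec.get("subsystem", "") or "",
                gpr=gpr,
            )
        )
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, id=data.get("id", path.stem)
    )


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Emit a BiGG-JSON file that round-trips through :func:`read_model_json`."""
    data = {
        "id": model.id,
        "metabolites": [{"id": m} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_reaction_rule": r.gpr.to_string(),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_sbml(path: str | Path) -> MetabolicModel:
    """Best-effort SBML Level 3 + FBC reader (delegates to COBRApy)."""
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover - cobra is an optional extra
        raise ImportError(
            "SBML reading requires the optional 'cobra' dependency"
        ) from exc
    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [m.id for m in cm.metabolites]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            subsystem=r.subsystem or "",
            gpr=parse_gpr(r.gene_reaction_rule or ""),
        )
        for r in cm.reactions
    ]
    return MetabolicModel(metabolites=metabolites, reactions=reactions, id=cm.id or "sbml")


# ---------------------------------------------------------------------------
# Toy model builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SentinelSpec:
    """A named branch reaction gated by a single dedicated gene."""

    reaction_id: str
    gene: str
    subsystem: str
    substrate: str


#: Branch reactions reusing BiGG ids of lipid-metabolic reactions that the
#: differential-flux analysis is expected to recover when their gating genes
#: are perturbed.
DEFAULT_SENTINELS: tuple[SentinelSpec, ...] = (
    SentinelSpec("PSDm_hs", "PISD_toy", "Glycerophospholipid metabolism", "ps_c"),
    SentinelSpec("PETOHMr_hs", "PEMT_toy", "Glycerophospholipid metabolism", "pe_c"),
    SentinelSpec("DHCRD2", "DEGS1_toy", "Sphingolipid metabolism", "dhcer_c"),
    SentinelSpec("DESAT18_3", "SCD_toy", "Fatty acid metabolism", "stcoa_c"),
    SentinelSpec("FAEL183", "ELOVL5_toy", "Fatty acid elongation", "lnlccoa_c"),
    SentinelSpec("SQLEr", "SQLE_toy", "Cholesterol metabolism", "sql_c"),
)


@dataclass
class ToyModelSpec:
    """Configuration for :func:`build_toy_model`."""

    sentinels: tuple[SentinelSpec, ...] = DEFAULT_SENTINELS
    n_extra_branches: int = 0
    include_dead_end: bool = False
    default_ub: float = 1000.0
    atp_sink_ub: float = 50000.0


def build_toy_model(spec: ToyModelSpec | None = None) -> MetabolicModel:
    """Build a small, feasible model spanning the nine energy subsystems.

    The core is a glucose -> acetyl-CoA -> NADH -> ATP backbone with
    fatty-acid and CoA turnover cycles; every energy subsystem carries at
    least one reaction.  Each sentinel is a single-gene-gated branch
    conversion (substrate -> ATP) so that branch throughput enters the
    maintenance objective and the gating gene's expression is the binding
    bottleneck for the branch flux.
    """
    spec = spec or ToyModelSpec()
    ub = spec.default_ub

    metabolites = [
        "glc_c",
        "accoa_c",
        "nadh_c",
        "nad_c",
        "atp_c",
        "o2_c",
        "pan_c",
        "coa_c",
        "pandeg_c",
        "fa_c",
    ]
    reactions: list[Reaction] = [
        Reaction("EX_glc", {"glc_c": -1.0}, -ub, 0.0),
        Reaction("EX_o2", {"o2_c": -1.0}, -ub, 0.0),
        Reaction("EX_pan", {"pan_c": -1.0}, -ub, 0.0),
        Reaction(
            "GLYC",
            {"glc_c": -1.0, "accoa_c": 2.0, "atp_c": 2.0, "nadh_c": 2.0},
            0.0,
            ub,
            "Glycolysis and Gluconeogenesis",
            parse_gpr("GAPDH_toy"),
        ),
        Reaction(
            "TCA",
            {"accoa_c": -1.0, "nadh_c": 2.0},
            0.0,
            ub,
            "Citric Acid Cycle",
            parse_gpr("CS_toy and ACO2_toy"),
        ),
        Reaction(
            "OXPHOS",
            {"nadh_c": -2.0, "o2_c": -1.0, "atp_c": 5.0},
            0.0,
            ub,
            "Oxidative Phosphorylation",
            parse_gpr("NDUFA_toy"),
        ),
        Reaction(
            "NADOX",
            {"nadh_c": -1.0, "nad_c": 1.0},
            0.0,
            ub,
            "NAD Metabolism",
            parse_gpr("NNT_toy"),
        ),
        Reaction("DM_nad", {"nad_c": -1.0}, 0.0, ub),
        Reaction(
            "COAS",
            {"pan_c": -1.0, "atp_c": -1.0, "coa_c": 1.0},
            0.0,
            ub,
            "CoA Synthesis",
            parse_gpr("PPAT_toy"),
        ),
        Reaction(
            "COADEG",
            {"coa_c": -1.0, "pandeg_c": 1.0},
            0.0,
            ub,
            "CoA Catabolism",
            parse_gpr("VNN1_toy or VNN2_toy"),
        ),
        Reaction("DM_pandeg", {"pandeg_c": -1.0}, 0.0, ub),
        Reaction(
            "FAS",
            {"accoa_c": -2.0, "atp_c": -1.0, "fa_c": 1.0},
            0.0,
            ub,
            "Fatty Acid Synthesis",
            parse_gpr("FASN_toy"),
        ),
        Reaction(
            "FAO",
            {"fa_c": -1.0, "accoa_c": 1.0, "nadh_c": 1.0},
            0.0,
            ub,
            "Fatty Acid Oxidation",
            parse_gpr("CPT1A_toy"),
        ),
        Reaction(
            "ATPM",
            {"atp_c": -1.0},
            0.0,
            spec.atp_sink_ub,
            "Biomass and Maintenance Functions",
        ),
    ]

    for sent in spec.sentinels:
        metabolites.append(sent.substrate)
        reactions.append(
            Reaction(f"EX_{sent.substrate[:-2]}", {sent.substrate: -1.0}, -ub, 0.0)
        )
        reactions.append(
            Reaction(
                sent.reaction_id,
                {sent.substrate: -1.0, "atp_c": 1.0},
                0.0,
                ub,
                sent.subsystem,
                parse_gpr(sent.gene),
            )
        )

    for i in range(spec.n_extra_branches):
        met = f"xb{i}_c"
        metabolites.append(met)
        reactions.append(Reaction(f"EX_xb{i}", {met: -1.0}, -ub, 0.0))
        reactions.append(Reaction(f"XB{i}", {met: -1.0, "atp_c": 1.0}, 0.0, ub))

    if spec.include_dead_end:
        metabolites.append("dead_c")
        reactions.append(
            Reaction("DEADEND", {"fa_c": -1.0, "dead_c": 1.0}, 0.0, ub)
        )

    model = MetabolicModel(metabolites=metabolites, reactions=reactions, id="toy")

    # Construction contract: the energy objective must admit a strictly
    # positive optimum under default bounds.
    from .flux_sim import FluxProblem, energy_objective, solve_sample_flux

    problem = FluxProblem.from_default_bounds(model, objective=energy_objective(model))
    solution = solve_sample_flux(problem)
    if not math.isfinite(solution.objective_value) or solution.objective_value <= 0:
        raise ToyModelError(
            "toy-model specification admits no positive steady-state energy flux"
        )
    return model
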