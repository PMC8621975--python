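"""Metabolic network representation and the thermodynamically consistent
parameterisation of all kinetic constants by independent basic variables.

Basic variables, in order:

* ``g_i`` — one per metabolite; a dimensionless chemical-potential-like term
  with ``ln Keq = -S^T g``, which makes cycle (Wegscheider) consistency of
  the equilibrium constants automatic.
* ``ln KM_{l,i}`` — one per (reaction, reactant) pair with nonzero
  stoichiometry, in ln(mM).
* ``ln kV_l`` — one per reaction (geometric mean of the two catalytic
  constants), in ln(1/s).

The full log-constant vector (Keq, KM, kV, kcat+, kcat-) is an exactly
linear function of the basic vector, so Haldane relationships hold by
construction for every basic vector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import sympy


class NetworkParseError(ValueError):
    """Raised when a network table or reaction formula cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a parsed network violates a structural invariant."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric network: metabolites x reactions.

    Attributes
    ----------
    metabolite_ids : list of str
    reaction_ids : list of str
    S : ndarray of int, shape (n_metabolites, n_reactions)
        Negative entries are consumed, positive produced.
    is_internal : ndarray of bool, per metabolite
        Internal metabolites are balanced at steady state; external ones
        are clamped.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    is_internal: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S)
        if not np.issubdtype(self.S.dtype, np.integer):
            if not np.allclose(self.S, np.round(self.S)):
                raise NetworkValidationError(
                    "stoichiometric coefficients must be integers"
                )
            self.S = np.round(self.S).astype(int)
        self.is_internal = np.asarray(self.is_internal, dtype=bool)
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise NetworkValidationError("S shape does not match id lists")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise NetworkValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise NetworkValidationError("duplicate reaction ids")
        for j, rid in enumerate(self.reaction_ids):
            col = self.S[:, j]
            if not np.any(col):
                raise NetworkValidationError(f"reaction {rid!r} has empty column")
            if not np.any(col < 0):
                raise NetworkValidationError(f"reaction {rid!r} has no substrate")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def S_internal(self) -> np.ndarray:
        """Rows of S for internal (balanced) metabolites."""
        return self.S[self.is_internal, :]

    @property
    def reactant_index(self) -> list[np.ndarray]:
        """Per reaction, indices of metabolites with nonzero stoichiometry."""
        return [np.flatnonzero(self.S[:, j]) for j in range(self.n_reactions)]

    def metabolite_index(self, met_id: str) -> int:
        return self.metabolite_ids.index(met_id)

    def reaction_index(self, rxn_id: str) -> int:
        return self.reaction_ids.index(rxn_id)


_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_][\w\-.\[\]]*)$")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a reaction formula like ``A + B <=> 2 C`` into a stoichiometry map.

    Returns a dict metabolite -> signed integer coefficient (substrates
    negative, products positive).
    """
    if "<=>" not in formula:
        raise NetworkParseError(f"formula lacks '<=>': {formula!r}")
    lhs, rhs = formula.split("<=>", 1)
    stoich: dict[str, int] = {}

    def _add(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            m = _TERM_RE.match(term)
            if m is None:
                raise NetworkParseError(f"cannot parse term {term!r} in {formula!r}")
            coeff = int(m.group(1)) if m.group(1) else 1
            met = m.group(2)
            stoich[met] = stoich.get(met, 0) + sign * coeff

    _add(lhs, -1)
    _add(rhs, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise NetworkParseError(f"empty or self-cancelling formula: {formula!r}")
    return stoich


def read_network(path) -> MetabolicNetwork:
    """Read a network from a tab-delimited, SBtab-flavoured file.

    The file contains a reaction table with columns ``!ID`` and
    ``!ReactionFormula`` and, optionally, a metabolite table with columns
    ``!ID`` and ``!IsConstant`` (1 marks an external/clamped metabolite).
    Tables are introduced by lines starting with ``!!`` carrying
    ``TableID='Reaction'`` or ``TableID='Compound'``; a file holding just
    a headerless reaction table (header row ``!ID\\t!ReactionFormula``) is
    also accepted, in which case all metabolites are internal.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    sections: dict[str, list[str]] = {}
    current: str | None = None
    implicit: list[str] = []
    for ln in lines:
        if not ln.strip():
            continue
        if ln.startswith("!!"):
            m = re.search(r"TableID='([^']+)'", ln)
            name = m.group(1) if m else f"table{len(sections)}"
            current = name
            sections[current] = []
        elif current is not None:
            sections[current].append(ln)
        else:
            implicit.append(ln)
    if not sections and implicit:
        sections["Reaction"] = implicit

    if "Reaction" not in sections:
        raise NetworkParseError(f"{path}: no reaction table found")

    def _parse_table(rows: list[str]) -> list[dict[str, str]]:
        header = rows[0].split("\t")
        out = []
        for row in rows[1:]:
            cells = row.split("\t")
            out.append({h: (cells[i] if i < len(cells) else "") for i, h in enumerate(header)})
        return out

    rxn_rows = _parse_table(sections["Reaction"])
    reaction_ids: list[str] = []
    stoichs: list[dict[str, int]] = []
    for i, row in enumerate(rxn_rows):
        rid = row.get("!ID", "").strip()
        formula = row.get("!ReactionFormula", "").strip()
        if not rid:
            raise NetworkParseError(f"{path}: reaction row {i + 1} lacks !ID")
        if not formula:
            raise NetworkParseError(f"{path}: reaction {rid!r} has empty formula")
        try:
            stoich = parse_formula(formula)
        except NetworkParseError as exc:
            raise NetworkParseError(f"{path}: reaction {rid!r}: {exc}") from exc
        if rid in reaction_ids:
            raise NetworkValidationError(f"{path}: duplicate reaction id {rid!r}")
        reaction_ids.append(rid)
        stoichs.append(stoich)

    external: set[str] = set()
    declared: list[str] = []
    if "Compound" in sections:
        for row in _parse_table(sections["Compound"]):
            mid = row.get("!ID", "").strip()
            if not mid:
                raise NetworkParseError(f"{path}: compound row lacks !ID")
            if mid in declared:
                raise NetworkValidationError(f"{path}: duplicate metabolite id {mid!r}")
            declared.append(mid)
            flag = row.get("!IsConstant", "0").strip().lower()
            if flag in ("1", "true", "yes"):
                external.add(mid)

    metabolite_ids = list(declared)
    for stoich in stoichs:
        for met in stoich:
            if met not in metabolite_ids:
                metabolite_ids.append(met)

    S = np.zeros((len(metabolite_ids), len(reaction_ids)), dtype=int)
    for j, stoich in enumerate(stoichs):
        for met, coeff in stoich.items():
            S[metabolite_ids.index(met), j] = coeff
    is_internal = np.array([m not in external for m in metabolite_ids])
    return MetabolicNetwork(metabolite_ids, reaction_ids, S, is_internal)


def write_network(network: MetabolicNetwork, path) -> None:
    """Write a network in the dialect accepted by :func:`read_network`."""
    with open(path, "w") as fh:
        fh.write("!!SBtab TableID='Reaction' TableType='Reaction'\n")
        fh.write("!ID\t!ReactionFormula\n")
        for j, rid in enumerate(network.reaction_ids):
            subs, prods = [], []
            for i in np.flatnonzero(network.S[:, j]):
                c = network.S[i, j]
                name = network.metabolite_ids[i]
                term = name if abs(c) == 1 else f"{abs(c)} {name}"
                (subs if c < 0 else prods).append(term)
            fh.write(f"{rid}\t{' + '.join(subs)} <=> {' + '.join(prods)}\n")
        fh.write("!!SBtab TableID='Compound' TableType='Compound'\n")
        fh.write("!ID\t!IsConstant\n")
        for i, mid in enumerate(network.metabolite_ids):
            fh.write(f"{mid}\t{0 if network.is_internal[i] else 1}\n")


@dataclass
class DependencySchema:
    """Linear map from basic variables to all log kinetic constants.

    The full vector ``q_all = M @ q_basic`` is laid out as
    ``[ln Keq (n_rxn), ln KM (n_km), ln kV (n_rxn), ln kcat+ (n_rxn),
    ln kcat- (n_rxn)]``.
    """

    network: MetabolicNetwork
    basic_names: list[str]
    km_pairs: list[tuple[int, int]]  # (reaction index, metabolite index)
    M: np.ndarray
    offset: np.ndarray

    # slices into the basic vector
    sl_g: slice = field(init=False)
    sl_km: slice = field(init=False)
    sl_kv: slice = field(init=False)
    # slices into q_all
    rows_keq: slice = field(init=False)
    rows_km: slice = field(init=False)
    rows_kv: slice = field(init=False)
    rows_kcat_fwd: slice = field(init=False)
    rows_kcat_bwd: slice = field(init=False)

    def __post_init__(self) -> None:
        n_met = self.network.n_metabolites
        n_km = len(self.km_pairs)
        n_rxn = self.network.n_reactions
        self.sl_g = slice(0, n_met)
        self.sl_km = slice(n_met, n_met + n_km)
        self.sl_kv = slice(n_met + n_km, n_met + n_km + n_rxn)
        self.rows_keq = slice(0, n_rxn)
        self.rows_km = slice(n_rxn, n_rxn + n_km)
        self.rows_kv = slice(n_rxn + n_km, 2 * n_rxn + n_km)
        self.rows_kcat_fwd = slice(2 * n_rxn + n_km, 3 * n_rxn + n_km)
        self.rows_kcat_bwd = slice(3 * n_rxn + n_km, 4 * n_rxn + n_km)

    @property
    def n_basic(self) -> int:
        return len(self.basic_names)

    @property
    def n_km(self) -> int:
        return len(self.km_pairs)

    def km_index(self, reaction: int, metabolite: int) -> int:
        """Position of a KM entry (within the KM block) for a reactant pair."""
        return self.km_pairs.index((reaction, metabolite))

    def expand_all(self, q_basic: np.ndarray) -> np.ndarray:
        q_basic = np.asarray(q_basic, dtype=float)
        if q_basic.shape != (self.n_basic,):
            raise ValueError(
                f"basic vector has length {q_basic.shape}, expected {self.n_basic}"
            )
        return self.M @ q_basic + self.offset

    # rows of M for single constants, used for data design matrices
    def design_row(self, kind: str, reaction: int, metabolite: int | None = None) -> np.ndarray:
        rows = {
            "keq": self.rows_keq,
            "kv": self.rows_kv,
            "kcat_fwd": self.rows_kcat_fwd,
            "kcat_bwd": self.rows_kcat_bwd,
        }
        if kind == "km":
            if metabolite is None:
                raise ValueError("km design row needs a metabolite")
            i = self.km_index(reaction, metabolite)
            return self.M[self.rows_km][i]
        return self.M[rows[kind]][reaction]


@dataclass
class KineticConstantSet:
    """Expanded log kinetic constants for one network.

    KM values are stored as a flat vector over the schema's
    (reaction, reactant) pairs.
    """

    schema: DependencySchema
    ln_keq: np.ndarray
    ln_km: np.ndarray
    ln_kv: np.ndarray
    ln_kcat_fwd: np.ndarray
    ln_kcat_bwd: np.ndarray

    def km_for_reaction(self, l: int) -> tuple[np.ndarray, np.ndarray]:
        """(metabolite indices, ln KM values) for reaction ``l``."""
        idx = [k for k, (rl, _) in enumerate(self.schema.km_pairs) if rl == l]
        mets = np.array([self.schema.km_pairs[k][1] for k in idx], dtype=int)
        return mets, self.ln_km[idx]

    def haldane_residual(self) -> float:
        """Max abs deviation from ln kcat+ - ln kcat- = ln Keq - sum_i S_il ln KM_il."""
        net = self.schema.network
        res = 0.0
        for l in range(net.n_reactions):
            mets, lnkm = self.km_for_reaction(l)
            rhs = self.ln_keq[l] - float(net.S[mets, l] @ lnkm)
            lhs = self.ln_kcat_fwd[l] - self.ln_kcat_bwd[l]
            res = max(res, abs(lhs - rhs))
        return res


def build_schema(network: MetabolicNetwork) -> DependencySchema:
    """Construct the dependency schema for a network.

    Basic vector: ``[g (per metabolite), ln KM (per reactant pair),
    ln kV (per reaction)]``; its length is
    ``n_metabolites + n_KM_entries + n_reactions``.
    """
    n_met, n_rxn = network.n_metabolites, network.n_reactions
    km_pairs: list[tuple[int, int]] = []
    for l in range(n_rxn):
        for i in np.flatnonzero(network.S[:, l]):
            km_pairs.append((l, int(i)))
    n_km = len(km_pairs)
    n_basic = n_met + n_km + n_rxn

    basic_names = (
        [f"g:{m}" for m in network.metabolite_ids]
        + [
            f"lnKM:{network.reaction_ids[l]}:{network.metabolite_ids[i]}"
            for l, i in km_pairs
        ]
        + [f"lnkV:{r}" for r in network.reaction_ids]
    )

    n_all = 4 * n_rxn + n_km
    M = np.zeros((n_all, n_basic))
    # ln Keq = -S^T g
    M[0:n_rxn, 0:n_met] = -network.S.T
    # ln KM: identity on its basic block
    M[n_rxn : n_rxn + n_km, n_met : n_met + n_km] = np.eye(n_km)
    # ln kV: identity
    M[n_rxn + n_km : 2 * n_rxn + n_km, n_met + n_km :] = np.eye(n_rxn)
    # ln kcat+- = ln kV +- (ln Keq - sum_i S_il ln KM_il) / 2
    half = np.zeros((n_rxn, n_basic))
    half[:, 0:n_met] = -network.S.T
    for k, (l, i) in enumerate(km_pairs):
        half[l, n_met + k] = -network.S[i, l]
    half *= 0.5
    kv_block = M[n_rxn + n_km : 2 * n_rxn + n_km]
    M[2 * n_rxn + n_km : 3 * n_rxn + n_km] = kv_block + half
    M[3 * n_rxn + n_km : 4 * n_rxn + n_km] = kv_block - half

    return DependencySchema(
        network=network,
        basic_names=basic_names,
        km_pairs=km_pairs,
        M=M,
        offset=np.zeros(n_all),
    )


def expand_constants(schema: DependencySchema, q_basic: np.ndarray) -> KineticConstantSet:
    """Expand a basic vector into the full set of log kinetic constants."""
    q_all = schema.expand_all(q_basic)
    return KineticConstantSet(
        schema=schema,
        ln_keq=q_all[schema.rows_keq].copy(),
        ln_km=q_all[schema.rows_km].copy(),
        ln_kv=q_all[schema.rows_kv].copy(),
        ln_kcat_fwd=q_all[schema.rows_kcat_fwd].copy(),
        ln_kcat_bwd=q_all[schema.rows_kcat_bwd].copy(),
    )


def cycle_basis(S: np.ndarray) -> np.ndarray:
    """Integer-scaled null-space basis of a stoichiometric matrix.

    Returns an array of shape (n_reactions, n_cycles); empty second axis
    when the columns of S are independent. Basis vectors are rescaled to
    integers (smallest magnitude), so a 3-cycle yields (1, 1, 1).
    """
    mat = sympy.Matrix(S.astype(int))
    null = mat.nullspace()
    if not null:
        return np.zeros((S.shape[1], 0))
    cols = []
    for vec in null:
        denoms = [sympy.fraction(sympy.nsimplify(v))[1] for v in vec]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        v = np.array([float(x * scale) for x in vec])
        g = np.gcd.reduce(np.abs(np.round(v).astype(int))[np.round(v) != 0]) if np.any(v) else 1
        cols.append(v / max(g, 1))
    return np.column_stack(cols)


def check_wegscheider(
    ln_keq: np.ndarray,
    network: MetabolicNetwork,
    internal_only: bool = False,
) -> float:
    """Max absolute cycle residual ``|k^T ln Keq|`` over a null-space basis of S.

    By default cycles are taken from the full stoichiometric matrix (a closed
    thermodynamic cycle must balance every metabolite, clamped or not);
    ``internal_only=True`` restricts the rows to internal metabolites, which
    admits pseudo-cycles through external metabolites.
    """
    S = network.S_internal if internal_only else network.S
    K = cycle_basis(S)
    if K.shape[1] == 0:
        return 0.0
    return float(np.max(np.abs(K.T @ np.asarray(ln_keq, dtype=float))))
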