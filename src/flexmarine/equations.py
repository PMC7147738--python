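"""User-defined equation systems for pelagic, benthic and sediment models.

The framework ships no built-in biogeochemistry.  Constants, variables and
differential equations (dC/dt = RHS) are declared in the XML setup file,
parsed into expression trees and evaluated every time step on every active
cell.  The same expression engine drives agent traits in the ABM module.

Expression grammar (EBNF)::

    expr    = term { ("+" | "-") term } ;
    term    = unary { ("*" | "/") unary } ;
    unary   = "-" unary | power ;
    power   = atom [ "^" unary ] ;
    atom    = NUMBER | NAME | NAME "(" [ expr { "," expr } ] ")"
            | "(" cond ")" ;
    cond    = expr [ ("<" | ">" | "<=" | ">=" | "==") expr ] ;

Functions: exp, log, sqrt, min, max, abs, sin, cos, tanh, pow, step (unit
step, 1 for positive argument) and if(cond, a, b).  Comparisons evaluate to
0/1 and gate conditionals.  Evaluation is cell-local: spatial coupling is
the transport module's job.

Time integration is forward Euler by default (RK4 optional); vertical
settling, pelagic-benthic diffusive exchange and bottom-stress resuspension
are separate conservative operators applied after the reaction update.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh3D

ENVIRONMENT_NAMES = {"temp", "salt", "light", "depth", "bottom_stress",
                     "time", "x", "y", "z"}

_FUNCS = {
    "exp": np.exp, "log": np.log, "sqrt": np.sqrt, "abs": np.abs,
    "sin": np.sin, "cos": np.cos, "tanh": np.tanh,
    "min": np.minimum, "max": np.maximum, "pow": np.power,
    "step": lambda x: np.where(np.asarray(x) > 0, 1.0, 0.0),
    "if": lambda c, a, b: np.where(np.asarray(c) != 0, a, b),
}
_FUNC_ARITY = {"exp": 1, "log": 1, "sqrt": 1, "abs": 1, "sin": 1, "cos": 1,
               "tanh": 1, "step": 1, "min": 2, "max": 2, "pow": 2, "if": 3}


class DSLSyntaxError(ValueError):
    def __init__(self, text, pos, msg):
        super().__init__(f"syntax error in {text!r} at position {pos}: {msg}")
        self.text, self.pos = text, pos


class UndefinedSymbolError(KeyError):
    pass


class EquationError(RuntimeError):
    pass


class StiffnessWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# tokenizer + recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
                    r"|([A-Za-z_][A-Za-z_0-9]*)"
                    r"|(<=|>=|==|[-+*/^(),<>]))")


def _tokenize(text):
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise DSLSyntaxError(text, pos, f"unexpected {text[pos]!r}")
        num, name, op = m.groups()
        if num is not None:
            tokens.append(("num", float(num), m.start(1)))
        elif name is not None:
            tokens.append(("name", name, m.start(2)))
        else:
            tokens.append(("op", op, m.start(3)))
        pos = m.end()
    tokens.append(("end", None, len(text)))
    return tokens


class _Parser:
    def __init__(self, text):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op):
        kind, val, pos = self.next()
        if kind != "op" or val != op:
            raise DSLSyntaxError(self.text, pos, f"expected {op!r}")

    def parse(self):
        ast = self.cond()
        kind, val, pos = self.peek()
        if kind != "end":
            raise DSLSyntaxError(self.text, pos, f"unexpected {val!r}")
        return ast

    def cond(self):
        left = self.expr()
        kind, val, pos = self.peek()
        if kind == "op" and val in ("<", ">", "<=", ">=", "=="):
            self.next()
            right = self.expr()
            return ("cmp", val, left, right)
        return left

    def expr(self):
        node = self.term()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "+-":
                self.next()
                node = ("bin", val, node, self.term())
            else:
                return node

    def term(self):
        node = self.unary()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in "*/":
                self.next()
                node = ("bin", val, node, self.unary())
            else:
                return node

    def unary(self):
        kind, val, _ = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return ("neg", self.unary())
        return self.power()

    def power(self):
        node = self.atom()
        kind, val, _ = self.peek()
        if kind == "op" and val == "^":
            self.next()
            return ("bin", "^", node, self.unary())
        return node

    def atom(self):
        kind, val, pos = self.next()
        if kind == "num":
            return ("num", val)
        if kind == "name":
            k2, v2, _ = self.peek()
            if k2 == "op" and v2 == "(":
                if val not in _FUNCS:
                    raise DSLSyntaxError(self.text, pos,
                                         f"unknown function {val!r}")
                self.next()
                args = [self.cond()]
                while True:
                    k3, v3, p3 = self.next()
                    if k3 == "op" and v3 == ",":
                        args.append(self.cond())
                    elif k3 == "op" and v3 == ")":
                        break
                    else:
                        raise DSLSyntaxError(self.text, p3,
                                             "expected ',' or ')'")
                if len(args) != _FUNC_ARITY[val]:
                    raise DSLSyntaxError(
                        self.text, pos, f"{val} takes {_FUNC_ARITY[val]} "
                        f"argument(s), got {len(args)}")
                return ("call", val, args)
            return ("var", val)
        if kind == "op" and val == "(":
            node = self.cond()
            self.expect_op(")")
            return node
        raise DSLSyntaxError(self.text, pos, "expected a value")


_BINOPS = {"+": np.add, "-": np.subtract, "*": np.multiply,
           "/": np.divide, "^": np.power}
_CMPOPS = {"<": np.less, ">": np.greater, "<=": np.less_equal,
           ">=": np.greater_equal, "==": np.equal}


def _names_in(ast, out):
    tag = ast[0]
    if tag == "var":
        out.add(ast[1])
    elif tag == "bin" or tag == "cmp":
        _names_in(ast[2], out)
        _names_in(ast[3], out)
    elif tag == "neg":
        _names_in(ast[1], out)
    elif tag == "call":
        for a in ast[2]:
            _names_in(a, out)


def _eval_ast(ast, env):
    tag = ast[0]
    if tag == "num":
        return ast[1]
    if tag == "var":
        try:
            return env[ast[1]]
        except KeyError:
            raise UndefinedSymbolError(ast[1]) from None
    if tag == "neg":
        return -_eval_ast(ast[1], env)
    if tag == "bin":
        return _BINOPS[ast[1]](_eval_ast(ast[2], env), _eval_ast(ast[3], env))
    if tag == "cmp":
        return _CMPOPS[ast[1]](_eval_ast(ast[2], env),
                               _eval_ast(ast[3], env)).astype(float)
    if tag == "call":
        return _FUNCS[ast[1]](*[_eval_ast(a, env) for a in ast[2]])
    raise AssertionError(ast)


class Expression:
    """A parsed DSL expression, callable on an environment mapping."""

    def __init__(self, text: str):
        self.text = str(text).strip()
        self.ast = _Parser(self.text).parse()
        names: set = set()
        _names_in(self.ast, names)
        self.names = frozenset(names)

    def __call__(self, env: dict):
        return _eval_ast(self.ast, env)

    def __repr__(self):
        return f"Expression({self.text!r})"


# ---------------------------------------------------------------------------
# equation systems
# ---------------------------------------------------------------------------

@dataclass
class VariableSpec:
    name: str
    domain: str = "pelagic"              # pelagic | benthic
    advected: bool = False
    initial: object = 0.0                # value or per-cell field
    nonnegative: bool = False
    settling: object = 0.0               # m/s, number or Expression
    settle_target: str | None = None     # benthic variable receiving deposit
    # benthic-only: resuspension and exchange parameters
    tau_crit: float | None = None        # Pa
    erosion_rate: float = 0.0            # units / m^2 / s
    resuspend_target: str | None = None  # pelagic variable receiving erosion
    exchange_with: str | None = None     # (pelagic spec) benthic partner
    k_exchange: float = 0.0              # m/s
    mixing_depth: float = 0.1            # m, porewater-equivalent thickness


@dataclass
class EquationSystem:
    constants: dict = field(default_factory=dict)
    variables: dict = field(default_factory=dict)    # name -> VariableSpec
    equations: dict = field(default_factory=dict)    # name -> Expression
    auxiliaries: dict = field(default_factory=dict)  # name -> Expression
    aux_order: list = field(default_factory=list)

    def pelagic_names(self):
        return [n for n, v in self.variables.items() if v.domain == "pelagic"]

    def benthic_names(self):
        return [n for n, v in self.variables.items() if v.domain == "benthic"]

    def validate(self):
        errors = []
        known = (set(self.constants) | set(self.variables)
                 | set(self.auxiliaries) | ENVIRONMENT_NAMES)
        for name, expr in list(self.equations.items()) + list(
                self.auxiliaries.items()):
            for ref in expr.names:
                if ref not in known:
                    errors.append(
                        f"equation for {name!r} references undeclared "
                        f"symbol {ref!r}")
        for name in self.equations:
            if name not in self.variables:
                errors.append(f"equation given for undeclared variable "
                              f"{name!r}")
        for name, spec in self.variables.items():
            if spec.settle_target and spec.settle_target not in self.variables:
                errors.append(f"settling target {spec.settle_target!r} of "
                              f"{name!r} is not declared")
            if (spec.resuspend_target
                    and spec.resuspend_target not in self.variables):
                errors.append(f"resuspension target "
                              f"{spec.resuspend_target!r} of {name!r} is "
                              "not declared")
            if spec.exchange_with and spec.exchange_with not in self.variables:
                errors.append(f"exchange partner {spec.exchange_with!r} of "
                              f"{name!r} is not declared")
        self.aux_order = self._sort_auxiliaries(errors)
        if errors:
            raise EquationError("; ".join(errors))
        return self

    def _sort_auxiliaries(self, errors):
        order, state = [], {}

        def visit(n, stack):
            if state.get(n) == 2:
                return
            if state.get(n) == 1:
                cyc = stack[stack.index(n):] + [n]
                errors.append("cyclic auxiliary definitions: "
                              + " -> ".join(cyc))
                return
            state[n] = 1
            for dep in self.auxiliaries[n].names:
                if dep in self.auxiliaries:
                    visit(dep, stack + [n])
            state[n] = 2
            order.append(n)

        for n in self.auxiliaries:
            visit(n, [])
        return order

    def build_env(self, fields: dict, environment: dict | None = None) -> dict:
        env = dict(self.constants)
        env.update(fields)
        if environment:
            env.update(environment)
        env.setdefault("light", 0.0)
        env.setdefault("bottom_stress", 0.0)
        for name in self.aux_order:
            env[name] = self.auxiliaries[name](env)
        return env


# ---------------------------------------------------------------------------
# XML parsing
# ---------------------------------------------------------------------------

def _bool(s, default=False):
    if s is None:
        return default
    return str(s).strip().lower() in ("1", "true", "yes", "on")


def parse_equation_system(xml_setup) -> EquationSystem:
    """Parse <constants>, <pelagicvariables>, <benthicvariables>,
    <auxiliaries> and <equations> blocks into a validated system.

    Accepts an ``xml.etree.ElementTree.Element``, an XML string or a path.
    """
    import xml.etree.ElementTree as ET

    if isinstance(xml_setup, str):
        if xml_setup.lstrip().startswith("<"):
            root = ET.fromstring(xml_setup)
        else:
            root = ET.parse(xml_setup).getroot()
    else:
        root = xml_setup

    sys = EquationSystem()
    for c in root.iter("constant"):
        sys.constants[c.get("name")] = float(c.get("value"))

    for block, domain in (("pelagicvariables", "pelagic"),
                          ("benthicvariables", "benthic")):
        parent = root.find(block)
        if parent is None:
            continue
        for v in parent.iter("variable"):
            settling = v.get("settling", "0")
            try:
                settling_val: object = float(settling)
            except ValueError:
                settling_val = Expression(settling)
            spec = VariableSpec(
                name=v.get("name"), domain=domain,
                advected=_bool(v.get("advected")),
                initial=float(v.get("initial", "0")),
                nonnegative=_bool(v.get("nonnegative")),
                settling=settling_val,
                settle_target=v.get("settle_target"),
                tau_crit=(float(v.get("tau_crit"))
                          if v.get("tau_crit") else None),
                erosion_rate=float(v.get("erosion_rate", "0")),
                resuspend_target=v.get("resuspend_target"),
                exchange_with=v.get("exchange_with"),
                k_exchange=float(v.get("k_exchange", "0")),
                mixing_depth=float(v.get("mixing_depth", "0.1")))
            sys.variables[spec.name] = spec

    aux = root.find("auxiliaries")
    if aux is not None:
        for a in aux.iter("aux"):
            sys.auxiliaries[a.get("name")] = Expression(a.text or a.get("expr"))
    eqs = root.find("equations")
    if eqs is not None:
        for e in eqs.iter("equation"):
            sys.equations[e.get("variable")] = Expression(e.text
                                                          or e.get("expr"))
    return sys.validate()


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def _rhs(system: EquationSystem, fields, environment):
    env = system.build_env(fields, environment)
    out = {}
    for name, expr in system.equations.items():
        try:
            r = expr(env)
        except UndefinedSymbolError as e:
            raise EquationError(f"undefined symbol {e} in equation for "
                                f"{name!r}") from None
        out[name] = np.asarray(r, dtype=float)
    return out


def evaluate_timestep(system: EquationSystem, fields: dict,
                      environment: dict | None, dt: float, *,
                      method: str = "euler",
                      stiffness_warning: bool = True) -> dict:
    """Advance all state variables one reaction step (cell-local).

    fields maps variable name -> array (any shape); variables without an
    equation are diagnostic and pass through unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method == "euler":
        rhs = _rhs(system, fields, environment)
        new = dict(fields)
        for name, r in rhs.items():
            if not np.all(np.isfinite(r)):
                bad = np.argwhere(~np.isfinite(np.atleast_1d(r)))[0]
                raise EquationError(
                    f"non-finite RHS for {name!r} "
                    f"({system.equations[name].text}) at cell {tuple(bad)}")
            if stiffness_warning:
                c = np.asarray(fields[name], dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.abs(dt * r / np.where(np.abs(c) > 1e-30, c, np.inf))
                if np.any(ratio > 0.5):
                    warnings.warn(
                        f"|dt * RHS / {name}| exceeds 0.5; the forward-Euler "
                        "step may be too long for this system",
                        StiffnessWarning, stacklevel=2)
            new[name] = np.asarray(fields[name], dtype=float) + dt * r
    elif method == "rk4":
        def deriv(f):
            return _rhs(system, f, environment)

        k1 = deriv(fields)

        def shift(f, k, h):
            g = dict(f)
            for n in k:
                g[n] = np.asarray(f[n], float) + h * k[n]
            return g

        k2 = deriv(shift(fields, k1, dt / 2))
        k3 = deriv(shift(fields, k2, dt / 2))
        k4 = deriv(shift(fields, k3, dt))
        new = dict(fields)
        for name in k1:
            new[name] = (np.asarray(fields[name], float)
                         + dt / 6 * (k1[name] + 2 * k2[name]
                                     + 2 * k3[name] + k4[name]))
    else:
        raise ValueError(f"unknown integration method {method!r}")
    for name, spec in system.variables.items():
        if spec.nonnegative and name in new:
            new[name] = np.clip(new[name], 0.0, None)
    return new


# ---------------------------------------------------------------------------
# benthic stack and vertical transfers
# ---------------------------------------------------------------------------

@dataclass
class BenthicStack:
    """Per-polygon layered benthic variables in per-area units (e.g. g/m^2)."""

    fields: dict                      # name -> (P, Lb)
    n_layers: int = 1

    @classmethod
    def zeros(cls, system: EquationSystem, n_polygons: int,
              n_layers: int = 1) -> "BenthicStack":
        f = {}
        for name in system.benthic_names():
            init = system.variables[name].initial
            f[name] = np.full((n_polygons, n_layers), float(init))
        return cls(fields=f, n_layers=n_layers)

    def total(self, name, areas) -> float:
        return float(np.sum(self.fields[name].sum(axis=1) * areas))


def _settling_field(spec: VariableSpec, system, fields, environment, shape):
    w = spec.settling
    if isinstance(w, Expression):
        env = system.build_env(fields, environment)
        w = np.broadcast_to(np.asarray(w(env), dtype=float), shape)
    else:
        w = np.full(shape, float(w))
    if np.any(w < 0):
        raise EquationError(f"settling velocity of {spec.name!r} must be >= 0")
    return w


def apply_settling(system: EquationSystem, fields: dict, mesh: Mesh3D,
                   dt: float, benthic: BenthicStack | None = None,
                   environment: dict | None = None) -> dict:
    """Upwind vertical settling; bottom-cell flux deposits into the mapped
    benthic variable (per area).  Conserves the pelagic+benthic inventory.

    Sub-steps internally when w_s * dt exceeds the thinnest active layer.
    """
    new = dict(fields)
    areas = mesh.mesh2d.areas
    for name, spec in system.variables.items():
        if spec.domain != "pelagic" or name not in fields:
            continue
        c = np.asarray(new[name], dtype=float)
        if c.ndim != 2:
            continue
        w = _settling_field(spec, system, new, environment, c.shape)
        if not np.any(w > 0):
            continue
        if spec.settle_target and benthic is None:
            raise EquationError(f"settling target {spec.settle_target!r} "
                                "needs a benthic stack")
        hmin = mesh.cell_thickness[mesh.cell_active].min()
        nsub = max(1, int(np.ceil(float(w.max()) * dt / hmin)))
        dts = dt / nsub
        vol = mesh.cell_volume
        act = mesh.cell_active
        P, K = c.shape
        idx = np.arange(P)
        kb = mesh.bottom_layer
        for _ in range(nsub):
            # interface flux from layer k to k+1 where both active (m/s * conc)
            if K > 1:
                fl = w[:, :-1] * c[:, :-1] * areas[:, None]   # units/s
                fl = np.where(act[:, :-1] & act[:, 1:], fl, 0.0)
            mass = vol * c
            if K > 1:
                mass[:, :-1] -= dts * fl
                mass[:, 1:] += dts * fl
            # bottom-cell deposition
            cb = c[idx, kb]
            dep = w[idx, kb] * cb * dts                       # per area
            mass[idx, kb] -= dep * areas
            if spec.settle_target and benthic is not None:
                benthic.fields[spec.settle_target][:, 0] += dep
            c = np.where(act, mass / np.where(vol > 0, vol, 1.0), 0.0)
        new[name] = c

    # benthic-to-benthic settling (burial through the stack)
    if benthic is not None and benthic.n_layers > 1:
        for name, spec in system.variables.items():
            if spec.domain != "benthic":
                continue
            w = spec.settling
            if isinstance(w, Expression) or not w:
                continue
            B = benthic.fields[name]
            frac = min(1.0, float(w) * dt / max(spec.mixing_depth, 1e-12))
            move = frac * B[:, :-1]
            B[:, :-1] -= move
            B[:, 1:] += move
    return new


def resuspend(system: EquationSystem, fields: dict, benthic: BenthicStack,
              bottom_stress: np.ndarray, dt: float, mesh: Mesh3D) -> dict:
    """Erode benthic mass into the bottom pelagic cell where the bottom
    stress exceeds the critical value: E * (tau/tau_crit - 1), capped by the
    available benthic inventory.  Conservative."""
    new = dict(fields)
    tau = np.asarray(bottom_stress, dtype=float)
    P = mesh.n_polygons
    idx = np.arange(P)
    kb = mesh.bottom_layer
    vol_b = mesh.cell_volume[idx, kb]
    areas = mesh.mesh2d.areas
    for name, spec in system.variables.items():
        if (spec.domain != "benthic" or spec.tau_crit is None
                or not spec.resuspend_target):
            continue
        B = benthic.fields[name]
        excess = np.clip(tau / spec.tau_crit - 1.0, 0.0, None)
        erode = np.minimum(spec.erosion_rate * excess * dt, B[:, 0])
        B[:, 0] -= erode
        c = np.asarray(new[spec.resuspend_target], dtype=float).copy()
        c[idx, kb] += erode * areas / np.where(vol_b > 0, vol_b, 1.0)
        new[spec.resuspend_target] = c
    return new


def interface_exchange(system: EquationSystem, fields: dict,
                       benthic: BenthicStack, mesh: Mesh3D, dt: float) -> dict:
    """Diffusive pelagic-benthic exchange at the sediment-water interface.

    flux (per area) = k_ex * (c_pelagic_bottom - B_top / h_mix); the summed
    inventory of each linked pair is conserved exactly.
    """
    new = dict(fields)
    P = mesh.n_polygons
    idx = np.arange(P)
    kb = mesh.bottom_layer
    h_p = mesh.cell_thickness[idx, kb]
    for name, spec in system.variables.items():
        if spec.domain != "pelagic" or not spec.exchange_with:
            continue
        if spec.k_exchange < 0:
            raise EquationError("exchange coefficient must be >= 0")
        if spec.k_exchange == 0:
            continue
        bspec = system.variables[spec.exchange_with]
        B = benthic.fields[spec.exchange_with]
        c = np.asarray(new[name], dtype=float).copy()
        cb = c[idx, kb]
        c_eq = B[:, 0] / bspec.mixing_depth
        flux = spec.k_exchange * (cb - c_eq)          # units/m^2/s
        # cap so neither reservoir overshoots past equality in one step
        rate = spec.k_exchange * (1.0 / np.maximum(h_p, 1e-12)
                                  + 1.0 / bspec.mixing_depth)
        factor = np.where(rate * dt > 0,
                          (1.0 - np.exp(-rate * dt)) / (rate * dt), 1.0)
        flux = flux * factor
        c[idx, kb] = cb - flux * dt / np.maximum(h_p, 1e-12)
        B[:, 0] = B[:, 0] + flux * dt
        new[name] = c
    return new
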