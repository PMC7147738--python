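"""Equation DSL: parsing, evaluation, settling, resuspension, exchange."""

import numpy as np
import pytest

import flexmarine as fm
from flexmarine import equations as eq
from flexmarine.equations import (BenthicStack, DSLSyntaxError, EquationError,
                                  EquationSystem, Expression, VariableSpec,
                                  apply_settling, evaluate_timestep,
                                  interface_exchange, parse_equation_system,
                                  resuspend)

DAY = 86400.0


# ---------------------------------------------------------------------------
# expression engine
# ---------------------------------------------------------------------------

def test_michaelis_menten_demo_parses_and_evaluates():
    xml = """<model>
      <constants>
        <constant name="mu" value="2.0"/><constant name="k" value="0.5"/>
      </constants>
      <pelagicvariables><variable name="N" initial="1.0"/></pelagicvariables>
      <auxiliaries><aux name="uptake">mu*N/(N+k)</aux></auxiliaries>
      <equations><equation variable="N">-uptake</equation></equations>
    </model>"""
    system = parse_equation_system(xml)
    assert set(system.variables) == {"N"}
    env = system.build_env({"N": 1.5})
    assert env["uptake"] == pytest.approx(2.0 * 1.5 / 2.0)


def test_undeclared_symbol_is_named():
    xml = """<model>
      <pelagicvariables><variable name="N"/></pelagicvariables>
      <equations><equation variable="N">-Z*N</equation></equations>
    </model>"""
    with pytest.raises(EquationError, match="'Z'"):
        parse_equation_system(xml)


def test_syntax_error_reports_position():
    with pytest.raises(DSLSyntaxError, match="position"):
        Expression("1 + * 2")


def test_cyclic_auxiliaries_listed():
    xml = """<model>
      <auxiliaries>
        <aux name="a">b+1</aux><aux name="b">a+1</aux>
      </auxiliaries>
    </model>"""
    with pytest.raises(EquationError, match="cyclic"):
        parse_equation_system(xml)


def test_unknown_function_rejected():
    with pytest.raises(DSLSyntaxError, match="unknown function"):
        Expression("foo(2)")


@pytest.mark.parametrize("text,env,expected", [
    ("2^3^2", {}, 512.0),                         # right-associative power
    ("-2^2", {}, -4.0),                           # unary minus binds loosely
    ("min(3, max(1, 2))", {}, 2.0),
    ("step(0) + step(1e-12)", {}, 1.0),
    ("if(x > 1, 10, 20)", {"x": 0.5}, 20.0),
    ("abs(-3)/2 + pow(2, -1)", {}, 2.0),
    ("tanh(0) + cos(0) - sin(0)", {}, 1.0),
])
def test_expression_values(text, env, expected):
    assert Expression(text)(env) == pytest.approx(expected, rel=1e-12)


def test_random_expression_trees_match_direct_evaluation():
    """50 randomized expression trees (depth <= 5) evaluate identically to
    an independent recursive evaluation of the same tree."""
    rng = np.random.default_rng(2024)
    names = ["a", "b", "c"]

    def build(depth):
        # returns (dsl_text, direct_fn)
        if depth == 0 or rng.random() < 0.25:
            if rng.random() < 0.5:
                v = float(np.round(rng.uniform(0.1, 3.0), 3))
                return f"{v}", lambda e, v=v: v
            n = names[rng.integers(len(names))]
            return n, lambda e, n=n: e[n]
        kind = rng.integers(6)
        lt, lf = build(depth - 1)
        rt, rf = build(depth - 1)
        if kind == 0:
            return f"({lt}+{rt})", lambda e: lf(e) + rf(e)
        if kind == 1:
            return f"({lt}-{rt})", lambda e: lf(e) - rf(e)
        if kind == 2:
            return f"({lt}*{rt})", lambda e: lf(e) * rf(e)
        if kind == 3:
            return f"({lt}/({rt}+1.5))", lambda e: lf(e) / (rf(e) + 1.5)
        if kind == 4:
            return f"exp(-abs({lt}))", lambda e: np.exp(-abs(lf(e)))
        return f"min({lt},{rt})", lambda e: min(lf(e), rf(e))

    for _ in range(50):
        text, direct = build(5)
        expr = Expression(text)
        env = {n: float(np.round(rng.uniform(0.1, 2.0), 3)) for n in names}
        assert expr(env) == pytest.approx(direct(env), abs=1e-12)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def logistic_system(r, K):
    s = EquationSystem(constants={"r": r, "K": K},
                       variables={"P": VariableSpec("P")},
                       equations={"P": Expression("r*P*(1-P/K)")})
    return s.validate()


def test_logistic_matches_closed_form():
    """dP/dt = r P (1 - P/K), r = 0.1/d, K = 1, P0 = 0.01, dt = 0.01 d:
    within 0.1% of the closed form at t = 100 d."""
    r, K, P0 = 0.1 / DAY, 1.0, 0.01
    system = logistic_system(r, K)
    dt = 0.01 * DAY
    fields = {"P": np.array(P0)}
    n = int(100 * DAY / dt)
    for _ in range(n):
        fields = evaluate_timestep(system, fields, None, dt,
                                   stiffness_warning=False)
    t = n * dt
    exact = K / (1 + (K / P0 - 1) * np.exp(-r * t))
    assert float(fields["P"]) == pytest.approx(exact, rel=1e-3)


def test_zero_rhs_leaves_fields_unchanged():
    s = EquationSystem(variables={"A": VariableSpec("A")},
                       equations={"A": Expression("0*A")}).validate()
    f0 = {"A": np.array([1.0, 2.0, 3.0])}
    f1 = evaluate_timestep(s, f0, None, 1.0)
    assert np.array_equal(f1["A"], f0["A"])


def test_linear_oscillator_matches_exact_euler_recurrence():
    """dA/dt = B, dB/dt = -A under forward Euler: energy grows exactly as
    (1 + dt^2)^n; trajectory matches the scalar recurrence to 1e-12."""
    s = EquationSystem(variables={"A": VariableSpec("A"),
                                  "B": VariableSpec("B")},
                       equations={"A": Expression("B"),
                                  "B": Expression("-A")}).validate()
    dt = 0.01
    fields = {"A": np.array(1.0), "B": np.array(0.0)}
    a, b = 1.0, 0.0
    for n in range(1000):
        fields = evaluate_timestep(s, fields, None, dt)
        a, b = a + dt * b, b - dt * a
        assert float(fields["A"]) == pytest.approx(a, abs=1e-12)
        assert float(fields["B"]) == pytest.approx(b, abs=1e-12)
    energy = float(fields["A"])**2 + float(fields["B"])**2
    assert energy == pytest.approx((1 + dt**2) ** 1000, rel=1e-9)


def test_rk4_beats_euler_on_logistic():
    r, K = 1.0, 1.0
    system = logistic_system(r, K)
    dt, n = 0.1, 50
    exact = K / (1 + (K / 0.01 - 1) * np.exp(-r * n * dt))
    out = {}
    for method in ("euler", "rk4"):
        fields = {"P": np.array(0.01)}
        for _ in range(n):
            fields = evaluate_timestep(system, fields, None, dt,
                                       method=method,
                                       stiffness_warning=False)
        out[method] = abs(float(fields["P"]) - exact)
    assert out["rk4"] < out["euler"] * 1e-3


def test_nan_rhs_aborts_with_variable_name():
    s = EquationSystem(variables={"A": VariableSpec("A")},
                       equations={"A": Expression("log(A)")}).validate()
    with pytest.raises(EquationError, match="'A'"):
        evaluate_timestep(s, {"A": np.array(-1.0)}, None, 1.0,
                          stiffness_warning=False)


def test_stiffness_warning():
    s = EquationSystem(variables={"A": VariableSpec("A")},
                       equations={"A": Expression("-10*A")}).validate()
    with pytest.warns(eq.StiffnessWarning):
        evaluate_timestep(s, {"A": np.array(1.0)}, None, 1.0)


def test_0d_and_3d_zero_velocity_trajectories_identical():
    """Cell-locality: the same system run 0D and on a 3D mesh with no
    transport gives identical per-cell trajectories."""
    system = logistic_system(0.5 / DAY, 2.0)
    dt = 0.05 * DAY
    f0 = {"P": np.array(0.01)}
    f3 = {"P": np.full((9, 3), 0.01)}
    for _ in range(200):
        f0 = evaluate_timestep(system, f0, None, dt, stiffness_warning=False)
        f3 = evaluate_timestep(system, f3, None, dt, stiffness_warning=False)
    assert f3["P"] == pytest.approx(float(f0["P"]), rel=1e-15)


# ---------------------------------------------------------------------------
# settling
# ---------------------------------------------------------------------------

def sediment_system(w=1e-3, **kw):
    s = EquationSystem(
        variables={"c": VariableSpec("c", settling=w, settle_target="b",
                                     **kw),
                   "b": VariableSpec("b", domain="benthic")})
    return s.validate()


def test_settling_moves_inventory_to_benthos(column_mesh):
    """After H / w_s, at least 95% of a uniform tracer has deposited; the
    pelagic + benthic total is conserved to 1e-12."""
    w = 1e-3
    system = sediment_system(w)
    fields = {"c": np.ones((1, 100))}
    benthic = BenthicStack.zeros(system, 1)
    A = column_mesh.mesh2d.areas
    tot0 = float((fields["c"] * column_mesh.cell_volume).sum()
                 + benthic.total("b", A))
    t_clear = 100.0 / w
    dt = t_clear / 500
    for _ in range(500):
        fields = apply_settling(system, fields, column_mesh, dt,
                                benthic=benthic)
    tot1 = float((fields["c"] * column_mesh.cell_volume).sum()
                 + benthic.total("b", A))
    assert tot1 == pytest.approx(tot0, rel=1e-12)
    assert benthic.total("b", A) / tot0 > 0.95


def test_zero_settling_velocity_is_identity(column_mesh):
    system = sediment_system(0.0)
    c0 = np.random.default_rng(0).random((1, 100))
    fields = apply_settling(system, {"c": c0.copy()}, column_mesh, 100.0,
                            benthic=BenthicStack.zeros(system, 1))
    assert np.array_equal(fields["c"], c0)


def test_negative_settling_velocity_rejected(column_mesh):
    system = sediment_system(-1e-3)
    with pytest.raises(EquationError, match=">= 0"):
        apply_settling(system, {"c": np.ones((1, 100))}, column_mesh, 10.0,
                       benthic=BenthicStack.zeros(system, 1))


def test_grain_size_fractions_deposit_distance_ordering():
    """Coarse grains (fast settling) deposit closer to the release than
    fine grains in a uniform current."""
    from flexmarine import offline, transport

    mesh = fm.generate_fixture_mesh(
        "rect", nx=40, ny=1, dx=100.0, depth=20.0,
        layer_interfaces=np.linspace(0, 20, 5),
        open_edges=("west", "east"))
    u = offline.broadcast_profile(0.05, 90.0, mesh)
    flux = u * mesh.mesh2d.face_length[:, None] * mesh.face_layer_thickness
    system = EquationSystem(variables={
        "coarse": VariableSpec("coarse", settling=3.9e-3,
                               settle_target="dep_c"),
        "fine": VariableSpec("fine", settling=7.3e-5,
                             settle_target="dep_f"),
        "dep_c": VariableSpec("dep_c", domain="benthic"),
        "dep_f": VariableSpec("dep_f", domain="benthic")}).validate()
    fields = {"coarse": np.zeros((40, 4)), "fine": np.zeros((40, 4))}
    fields["coarse"][2, 0] = 1.0
    fields["fine"][2, 0] = 1.0
    benthic = BenthicStack.zeros(system, 40)
    dt = 600.0
    for _ in range(144):                        # one day
        for name in ("coarse", "fine"):
            fields[name] = transport.advect_diffuse_explicit(
                fields[name], flux, mesh, dt, boundary_values=0.0)
        fields = apply_settling(system, fields, mesh, dt, benthic=benthic)
    x = mesh.mesh2d.voronoi_points[:, 0]
    A = mesh.mesh2d.areas

    def com(name):
        d = benthic.fields[name][:, 0] * A
        return float((d * x).sum() / d.sum())

    release_x = x[2]
    assert benthic.total("dep_c", A) > 0
    assert com("dep_c") - release_x < com("dep_f") - release_x
    assert com("dep_c") - release_x < 2000.0    # within a couple of km


# ---------------------------------------------------------------------------
# resuspension
# ---------------------------------------------------------------------------

def resuspension_system(tau_crit=0.1, E=1e-4, w=0.0):
    s = EquationSystem(variables={
        "c": VariableSpec("c", settling=w, settle_target="b"),
        "b": VariableSpec("b", domain="benthic", tau_crit=tau_crit,
                          erosion_rate=E, resuspend_target="c")})
    return s.validate()


def test_no_resuspension_below_critical_stress():
    mesh = fm.generate_fixture_mesh("rect", nx=2, ny=2, dx=10.0, depth=5.0)
    system = resuspension_system(tau_crit=0.1)
    benthic = BenthicStack.zeros(system, 4)
    benthic.fields["b"][:] = 1.0
    fields = {"c": np.zeros((4, 1))}
    out = resuspend(system, fields, benthic, np.full(4, 0.05), 100.0, mesh)
    assert np.all(out["c"] == 0.0)
    assert np.all(benthic.fields["b"] == 1.0)


def test_resuspension_one_step_arithmetic():
    """tau = 2 tau_crit: eroded mass per area = E * dt, by hand."""
    mesh = fm.generate_fixture_mesh("rect", nx=1, ny=1, dx=10.0, depth=5.0)
    E, dt = 1e-4, 50.0
    system = resuspension_system(tau_crit=0.1, E=E)
    benthic = BenthicStack.zeros(system, 1)
    benthic.fields["b"][:] = 1.0
    fields = {"c": np.zeros((1, 1))}
    out = resuspend(system, fields, benthic, np.array([0.2]), dt, mesh)
    eroded = E * (0.2 / 0.1 - 1.0) * dt
    assert benthic.fields["b"][0, 0] == pytest.approx(1.0 - eroded)
    assert out["c"][0, 0] == pytest.approx(eroded * 100.0 / 500.0)


def test_settling_resuspension_equilibrium():
    """Single column: steady suspended concentration c* satisfies
    w_s c* = E (tau/tau_crit - 1)."""
    mesh = fm.generate_fixture_mesh("rect", nx=1, ny=1, dx=10.0, depth=5.0)
    w, E, tau, tau_c = 1e-4, 1e-5, 0.3, 0.1
    system = resuspension_system(tau_crit=tau_c, E=E, w=w)
    benthic = BenthicStack.zeros(system, 1)
    benthic.fields["b"][:] = 10.0
    fields = {"c": np.zeros((1, 1))}
    dt = 500.0
    for _ in range(2000):
        fields = apply_settling(system, fields, mesh, dt, benthic=benthic)
        fields = resuspend(system, fields, benthic, np.array([tau]), dt,
                           mesh)
    c_star = E * (tau / tau_c - 1.0) / w
    assert fields["c"][0, 0] == pytest.approx(c_star, rel=1e-6)


# ---------------------------------------------------------------------------
# pelagic-benthic exchange
# ---------------------------------------------------------------------------

def exchange_system(k_ex, h_mix=0.5):
    s = EquationSystem(variables={
        "c": VariableSpec("c", exchange_with="b", k_exchange=k_ex),
        "b": VariableSpec("b", domain="benthic", mixing_depth=h_mix)})
    return s.validate()


def test_exchange_zero_flux_at_equal_effective_concentration():
    mesh = fm.generate_fixture_mesh("rect", nx=1, ny=1, dx=10.0, depth=2.0)
    system = exchange_system(1e-4, h_mix=0.5)
    benthic = BenthicStack.zeros(system, 1)
    benthic.fields["b"][:] = 1.5            # per area; /0.5 m -> c_eq = 3.0
    fields = {"c": np.full((1, 1), 3.0)}
    out = interface_exchange(system, fields, benthic, mesh, 100.0)
    assert out["c"][0, 0] == pytest.approx(3.0, abs=1e-15)
    assert benthic.fields["b"][0, 0] == pytest.approx(1.5, abs=1e-15)


def test_exchange_disabled_at_zero_coefficient():
    mesh = fm.generate_fixture_mesh("rect", nx=1, ny=1, dx=10.0, depth=2.0)
    system = exchange_system(0.0)
    benthic = BenthicStack.zeros(system, 1)
    benthic.fields["b"][:] = 9.0
    fields = {"c": np.zeros((1, 1))}
    out = interface_exchange(system, fields, benthic, mesh, 1e6)
    assert out["c"][0, 0] == 0.0


def test_two_box_exchange_relaxation_rate():
    """The pelagic-benthic pair relaxes exponentially with rate
    k_ex (1/h_p + 1/h_b), matching the two-box ODE within 0.5%."""
    h_p, h_b, k_ex = 2.0, 0.5, 1e-4
    mesh = fm.generate_fixture_mesh("rect", nx=1, ny=1, dx=10.0, depth=h_p)
    system = exchange_system(k_ex, h_mix=h_b)
    benthic = BenthicStack.zeros(system, 1)
    fields = {"c": np.full((1, 1), 1.0)}
    rate = k_ex * (1 / h_p + 1 / h_b)
    dt, n = 400.0, 40
    tot0 = fields["c"][0, 0] * h_p + benthic.fields["b"][0, 0]
    for _ in range(n):
        fields = interface_exchange(system, fields, benthic, mesh, dt)
    t = n * dt
    # equilibrium: c_eq shared; deviation decays as exp(-rate t)
    c_inf = tot0 / (h_p + h_b)
    expected = c_inf + (1.0 - c_inf) * np.exp(-rate * t)
    assert fields["c"][0, 0] == pytest.approx(expected, rel=5e-3)
    tot1 = fields["c"][0, 0] * h_p + benthic.fields["b"][0, 0]
    assert tot1 == pytest.approx(tot0, rel=1e-12)


def test_closed_pair_conserves_total_over_long_run():
    """Reaction transfers + settling + exchange conserve the summed
    inventory over 10^4 steps."""
    mesh = fm.generate_fixture_mesh("rect", nx=1, ny=1, dx=10.0, depth=5.0,
                                    layer_interfaces=np.linspace(0, 5, 6))
    system = EquationSystem(
        constants={"k": 1e-4},
        variables={"c": VariableSpec("c", settling=1e-5, settle_target="b",
                                     exchange_with="b", k_exchange=1e-5),
                   "b": VariableSpec("b", domain="benthic",
                                     tau_crit=0.1, erosion_rate=1e-6,
                                     resuspend_target="c")},
        equations={"c": Expression("0*c")}).validate()
    fields = {"c": np.ones((1, 5))}
    benthic = BenthicStack.zeros(system, 1)
    A = mesh.mesh2d.areas
    tot0 = float((fields["c"] * mesh.cell_volume).sum()
                 + benthic.total("b", A))
    tau = np.array([0.25])
    for _ in range(10_000):
        fields = evaluate_timestep(system, fields, None, 10.0,
                                   stiffness_warning=False)
        fields = apply_settling(system, fields, mesh, 10.0, benthic=benthic)
        fields = resuspend(system, fields, benthic, tau, 10.0, mesh)
        fields = interface_exchange(system, fields, benthic, mesh, 10.0)
    tot1 = float((fields["c"] * mesh.cell_volume).sum()
                 + benthic.total("b", A))
    assert tot1 == pytest.approx(tot0, rel=1e-10)
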