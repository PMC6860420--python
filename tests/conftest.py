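import numpy as np
import pytest

from macpol import build_full_model, equilibrate


@pytest.fixture(scope="session")
def full_model():
    return build_full_model()


@pytest.fixture(scope="session")
def full_baseline(full_model):
    """Equilibrated unstimulated normoxic state, shared across the session."""
    return equilibrate(full_model, residual_tol=1e-8)


@pytest.fixture(scope="session")
def full_at_baseline(full_model, full_baseline):
    return full_model.with_initial_state(full_baseline)


def random_toy_network(rng: np.random.Generator):
    """Random small network for RHS-oracle equivalence tests."""
    from macpol import ModelDefinition, ParameterSet, RateLaw, ReactionDef, SpeciesDef

    n_species = int(rng.integers(2, 9))
    ids = [f"S{i}" for i in range(n_species)]
    species = [SpeciesDef(s, group_id=s, initial_copies=float(rng.uniform(0, 50)))
               for s in ids]
    n_reactions = int(rng.integers(1, 11))
    reactions = []
    params = {}
    for j in range(n_reactions):
        kind = rng.choice(["mass_action_irreversible", "mass_action_reversible",
                           "hill_activation", "hill_inhibition"])
        picks = rng.permutation(n_species)
        reactants = tuple((ids[i], int(rng.integers(1, 3)))
                          for i in picks[: rng.integers(0, 3)])
        products = tuple((ids[i], int(rng.integers(1, 3)))
                         for i in picks[2: 2 + rng.integers(0, 3)])
        if not reactants and not products:
            products = ((ids[int(picks[0])], 1),)
        mod_pool = [s for s in ids if s not in {r for r, _ in reactants}]
        modifiers = tuple(rng.choice(mod_pool,
                                     size=min(len(mod_pool), rng.integers(0, 2)),
                                     replace=False))
        if kind == "mass_action_irreversible":
            labels = (f"k{j}",)
            params[f"k{j}"] = float(rng.uniform(0.01, 5))
            law = RateLaw(kind, labels, modifiers=modifiers)
        elif kind == "mass_action_reversible":
            labels = (f"kf{j}", f"kr{j}")
            params[f"kf{j}"] = float(rng.uniform(0.01, 5))
            params[f"kr{j}"] = float(rng.uniform(0.01, 5))
            law = RateLaw(kind, labels, modifiers=modifiers)
        else:
            labels = (f"v{j}", f"K{j}", f"n{j}")
            params[f"v{j}"] = float(rng.uniform(0.1, 10))
            params[f"K{j}"] = float(rng.uniform(1, 30))
            params[f"n{j}"] = float(rng.integers(1, 4))
            law = RateLaw(kind, labels, regulator=ids[int(picks[-1])],
                          modifiers=modifiers)
        reactions.append(ReactionDef(f"r{j}", reactants, products, law))
    return ModelDefinition(species, reactions, ParameterSet(params),
                           name="random_toy")


def brute_force_rhs(model, state):
    """Independent per-reaction summation oracle for the derivative vector.

    Recomputes every rate from the rate-law definition directly, without the
    compiled RHS machinery.
    """
    idx = {s.id: i for i, s in enumerate(model.species)}
    x = np.maximum(np.asarray(state, float), 0.0)
    dx = np.zeros(len(model.species))
    p = model.parameters
    for r in model.reactions:
        law = r.rate_law
        fwd = 1.0
        for sp, c in r.reactants:
            fwd *= x[idx[sp]] ** c
        for m in law.modifiers:
            fwd *= x[idx[m]]
        if law.kind == "mass_action_irreversible":
            rate = p[law.param_labels[0]] * fwd
        elif law.kind == "mass_action_reversible":
            rev = 1.0
            for sp, c in r.products:
                rev *= x[idx[sp]] ** c
            for m in law.modifiers:
                rev *= x[idx[m]]
            rate = p[law.param_labels[0]] * fwd - p[law.param_labels[1]] * rev
        else:
            v, K = p[law.param_labels[0]], p[law.param_labels[1]]
            n = p[law.param_labels[2]] if len(law.param_labels) == 3 else 1.0
            xr = x[idx[law.regulator]]
            num = xr ** n if law.kind == "hill_activation" else K ** n
            rate = v * num / (K ** n + xr ** n) * fwd
        for sp, c in r.reactants:
            dx[idx[sp]] -= c * rate
        for sp, c in r.products:
            dx[idx[sp]] += c * rate
    for i, s in enumerate(model.species):
        if s.is_buffered:
            dx[i] = 0.0
    return dx
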