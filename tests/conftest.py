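import pytest

from seedkit import build_problem, generate_fixture, generate_random_network


@pytest.fixture
def trap():
    return generate_fixture("trap")


@pytest.fixture
def linear3():
    return generate_fixture("linear3")


@pytest.fixture
def fig1_like():
    return generate_fixture("fig1_like")


@pytest.fixture
def accumulation_chain():
    return generate_fixture("accumulation_chain")


def bounded_random_problems(solve, n_networks, max_free, gen_kwargs, start_seed=0,
                            **problem_kwargs):
    """Deterministically scan generator seeds, keeping the first
    ``n_networks`` whose free candidate pool fits the brute-force oracle."""
    found = []
    seed = start_seed
    while len(found) < n_networks:
        net = generate_random_network(seed=seed, **gen_kwargs)
        prob = build_problem(net, solve=solve, max_solutions=10**6, **problem_kwargs)
        if len(prob.candidates - prob.forced_seeds) <= max_free:
            found.append((seed, net, prob))
        seed += 1
        if seed > start_seed + 50 * n_networks:
            raise RuntimeError("generator parameters yield too few small instances")
    return found


def seed_sets(result):
    return {sol.seeds for sol in result.solutions}
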