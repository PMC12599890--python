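import numpy as np
import pytest
from scipy.integrate import quad

import ecgssm.autograd as ag
from ecgssm.ssm import DiscreteSSM, discretize_zoh, ssm_scan


def loop_scan(A_d, B_d, C_d, u, h0=None, literal=False):
    """Literal unrolled recurrence, the independent oracle for ssm_scan."""
    N, d = B_d.shape
    h = np.zeros(N) if h0 is None else h0.astype(float).copy()
    y = []
    for n in range(u.shape[0]):
        if literal:
            y.append(C_d @ h)
            h = A_d * h + B_d @ u[n]
        else:
            h = A_d * h + B_d @ u[n]
            y.append(C_d @ h)
    return np.array(y)


class TestDiscretizeZOH:
    def test_zero_A_limit(self):
        d = discretize_zoh(np.array([0.0]), np.array([[2.0, -1.0]]), 0.3)
        assert d.A_d == pytest.approx(1.0)
        assert np.allclose(d.B_d, 0.3 * np.array([[2.0, -1.0]]))

    def test_A_minus_one_delta_ln2(self):
        # integral of e^{-tau} over [0, ln 2] is exactly 1/2
        d = discretize_zoh(np.array([-1.0]), np.array([[1.0]]), np.log(2))
        assert d.A_d == pytest.approx(0.5)
        assert d.B_d[0, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_B_d_matches_numeric_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        N, dim = 4, 3
        A = -rng.uniform(0.1, 3.0, size=N)
        B = rng.normal(size=(N, dim))
        delta = rng.uniform(0.05, 0.5)
        d = discretize_zoh(A, B, delta)
        for i in range(N):
            integral = quad(lambda tau: np.exp(A[i] * tau), 0, delta)[0]
            assert np.allclose(d.B_d[i], integral * B[i], rtol=1e-6)
        assert np.allclose(d.A_d, np.exp(A * delta))

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            discretize_zoh(np.array([-1.0]), np.array([[1.0]]), 0.0)

    def test_discretization_limit_recovers_A(self):
        A = np.array([-0.5, -2.0, -7.0])
        for delta in (1e-3, 1e-4, 1e-5):
            d = discretize_zoh(A, np.ones((3, 1)), delta)
            err = np.abs((d.A_d - 1) / delta - A).max()
            assert err < 10 * np.abs(A).max() ** 2 * delta   # O(delta)


class TestSSMScan:
    def _random_system(self, rng, N, d):
        A_d = rng.uniform(-0.9, 0.9, size=N)
        B_d = rng.normal(size=(N, d))
        C_d = rng.normal(size=(d, N))
        return DiscreteSSM(A_d=A_d, B_d=B_d, C_d=C_d)

    def test_zero_input_zero_state_gives_zero_output(self, rng):
        params = self._random_system(rng, 3, 2)
        assert np.all(ssm_scan(params, np.zeros((10, 2))) == 0)

    def test_memoryless_limit_impulse(self):
        # A_d = 0: y[n] = C * B_d * u[n] under the absorb convention
        params = DiscreteSSM(A_d=np.array([0.0]), B_d=np.array([[2.0]]),
                             C_d=np.array([[3.0]]))
        u = np.zeros((5, 1))
        u[0] = 1.0
        y = ssm_scan(params, u)
        assert y[0, 0] == pytest.approx(6.0)
        assert np.all(y[1:] == 0)

    def test_geometric_impulse_response(self):
        a, b, c = 0.7, 1.3, -0.4
        params = DiscreteSSM(A_d=np.array([a]), B_d=np.array([[b]]),
                             C_d=np.array([[c]]))
        u = np.zeros((12, 1))
        u[0] = 1.0
        y = ssm_scan(params, u)[:, 0]
        expected = c * a ** np.arange(12) * b
        assert np.allclose(y, expected, atol=1e-12)

    def test_literal_convention_delays_output_by_one(self, rng):
        params = self._random_system(rng, 4, 3)
        u = rng.normal(size=(16, 3))
        literal = ssm_scan(params, u, convention="literal")
        assert np.all(literal[0] == 0)               # y[0] reads h[0] = 0
        absorb = ssm_scan(params, u)
        assert np.allclose(literal[1:], absorb[:-1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_unrolled_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(1, 9))
        d = int(rng.integers(1, 5))
        L = int(rng.integers(1, 65))
        params = self._random_system(rng, N, d)
        u = rng.normal(size=(L, d))
        h0 = rng.normal(size=N)
        for literal in (False, True):
            conv = "literal" if literal else "absorb"
            got = ssm_scan(params, u, h0=h0, convention=conv)
            want = loop_scan(params.A_d, params.B_d, params.C_d, u, h0,
                             literal)
            assert np.abs(got - want).max() < 1e-10

    def test_stability_over_long_sequences(self, rng):
        """With |A_d| < 1 and bounded inputs, outputs stay bounded at
        L = 10,000 steps."""
        A = -rng.uniform(0.1, 2.0, size=6)
        d = discretize_zoh(A, rng.normal(size=(6, 2)), 0.05)
        d.C_d = rng.normal(size=(2, 6))
        u = rng.uniform(-1, 1, size=(10_000, 2))
        y = ssm_scan(d, u)
        assert np.isfinite(y).all()
        # geometric-series bound on the state keeps outputs bounded
        bound = (np.abs(d.C_d).sum() * np.abs(d.B_d).sum()
                 / (1 - np.abs(d.A_d).max()))
        assert np.abs(y).max() < bound

    def test_shape_mismatch_rejected(self, rng):
        params = self._random_system(rng, 3, 2)
        with pytest.raises(ValueError):
            ssm_scan(params, np.zeros((5, 4)))


class TestBatchedSelectiveScan:
    """The fused autograd primitive against the reference sequential scan."""

    def test_constant_parameters_reduce_to_reference_scan(self, rng):
        L, N = 20, 3
        A = -rng.uniform(0.2, 2.0, size=(1, N))
        B0, C0 = rng.normal(size=N), rng.normal(size=N)
        delta = 0.1
        u = rng.normal(size=(1, L, 1))
        y = ag.selective_scan(
            ag.Tensor(u), ag.Tensor(np.full((1, L, 1), delta)),
            ag.Tensor(np.tile(B0, (1, L, 1))), ag.Tensor(np.tile(C0, (1, L, 1))),
            ag.Tensor(A)).data
        disc = discretize_zoh(A[0], B0[:, None], delta)
        disc.C_d = C0[None, :]
        want = ssm_scan(disc, u[0])
        assert np.abs(y[0] - want).max() < 1e-12

    @pytest.mark.parametrize("name", ["u", "delta", "Bm", "Cm", "A"])
    def test_backward_matches_finite_differences(self, name):
        rng = np.random.default_rng(7)
        B, L, E, N = 2, 4, 3, 2
        tensors = {
            "u": ag.Tensor(rng.normal(size=(B, L, E)), requires_grad=True),
            "delta": ag.Tensor(rng.uniform(0.01, 0.2, size=(B, L, E)),
                               requires_grad=True),
            "Bm": ag.Tensor(rng.normal(size=(B, L, N)), requires_grad=True),
            "Cm": ag.Tensor(rng.normal(size=(B, L, N)), requires_grad=True),
            "A": ag.Tensor(-rng.uniform(0.5, 2, size=(E, N)),
                           requires_grad=True),
        }

        def loss():
            y = ag.selective_scan(*tensors.values())
            return ag.tsum(ag.mul(y, y))

        loss().backward()
        t = tensors[name]
        eps, num = 1e-6, np.zeros_like(t.data)
        it = np.nditer(t.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = t.data[i]
            t.data[i] = orig + eps
            up = loss().data
            t.data[i] = orig - eps
            down = loss().data
            t.data[i] = orig
            num[i] = (up - down) / (2 * eps)
        rel = np.abs(num - t.grad).max() / (np.abs(num).max() + 1e-12)
        assert rel < 1e-6


class TestAutogradPrimitives:
    def _gradcheck(self, build, tensors, tol=1e-6):
        build().backward()
        for t in tensors:
            num = np.zeros_like(t.data)
            it = np.nditer(t.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = t.data[i]
                t.data[i] = orig + 1e-6
                up = build().data
                t.data[i] = orig - 1e-6
                down = build().data
                t.data[i] = orig
                num[i] = (up - down) / 2e-6
            rel = np.abs(num - t.grad).max() / (np.abs(num).max() + 1e-12)
            assert rel < tol
            t.grad = None

    def test_conv1d_gradients(self):
        rng = np.random.default_rng(3)
        x = ag.Tensor(rng.normal(size=(2, 3, 14)), requires_grad=True)
        w = ag.Tensor(rng.normal(size=(4, 3, 5)), requires_grad=True)
        b = ag.Tensor(rng.normal(size=4), requires_grad=True)
        weights = np.arange(2 * 4 * 4, dtype=float).reshape(2, 4, 4)

        def build():
            return ag.tsum(ag.mul(ag.conv1d(x, w, b, stride=3),
                                  ag.Tensor(weights)))

        self._gradcheck(build, [x, w, b])

    def test_composed_mlp_gradients(self):
        rng = np.random.default_rng(4)
        x = ag.Tensor(rng.normal(size=(5, 3)), requires_grad=True)
        w = ag.Tensor(rng.normal(size=(3, 2)), requires_grad=True)

        def build():
            h = ag.softplus(ag.matmul(x, w))
            return ag.tmean(ag.mul(ag.sigmoid(h), ag.relu(ag.add(h, -0.5))))

        self._gradcheck(build, [x, w], tol=1e-5)

    def test_bce_with_logits_matches_manual_formula(self):
        rng = np.random.default_rng(5)
        logits = ag.Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        targets = rng.uniform(size=(4, 3))
        loss = ag.bce_with_logits(logits, targets)
        p = 1 / (1 + np.exp(-logits.data))
        manual = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).mean()
        assert loss.data == pytest.approx(manual, rel=1e-12)
        loss.backward()
        grad_manual = (p - targets) / targets.size
        assert np.allclose(logits.grad, grad_manual, atol=1e-12)
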