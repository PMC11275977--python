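import shutil
import subprocess
import textwrap

import numpy as np
import pytest

import phenolatency as ph
from phenolatency.params import alpha_of_tau


def season(params, s_hat, v0, taus, step=1e-3):
    state = ph.SeasonState(0, s_hat, np.atleast_1d(np.asarray(v0, float)))
    return ph.simulate_season(state, np.atleast_1d(np.asarray(taus, float)), params, step=step)


class TestClosedForms:
    def test_pure_decay_without_transmission(self, semel_params):
        """With beta=0 the parasite decouples and decays as v0*exp(-delta*T)."""
        p = semel_params.replace(beta=0.0)
        traj = season(p, 1e7, 1e5, 1.0)
        assert traj.v[0, -1] / 1e5 == pytest.approx(np.exp(-4.0), rel=1e-3)
        assert traj.v[0, -1] / 1e5 == pytest.approx(0.018316, rel=1e-4)

    def test_disease_free_host_cohort(self, semel_params):
        """No parasites: s(T) solves the linear emergence/death equation."""
        traj = season(semel_params, 1e7, 0.0, 1.0)
        k = ph.disease_free_cohort_factor(semel_params)
        assert 1e7 * k == pytest.approx(4.180e6, rel=1e-3)  # closed form itself
        assert traj.s[-1] == pytest.approx(1e7 * k, rel=1e-3)

    def test_latency_longer_than_season_never_releases(self, semel_params):
        traj = season(semel_params, 1e7, 1e6, 4.5)
        v = traj.v[0]
        assert v[-1] < 1e6 * np.exp(-semel_params.delta * semel_params.T)
        assert np.all(np.diff(v) <= 1e-9)  # monotone decay, no release wave


class TestStateInvariants:
    @pytest.mark.parametrize("mode", ["semelparous", "iteroparous"])
    def test_nonnegative_and_initial_conditions(self, mode):
        p = ph.default_parameters(mode)
        traj = season(p, 1e6, [1e5, 2e4], [1.0, 2.2])
        assert traj.s[0] == 0.0
        assert np.allclose(traj.v[:, 0], [1e5, 2e4])
        for arr in (traj.s, traj.r, traj.v):
            assert np.all(arr >= 0.0)
        if traj.i is not None:
            assert np.all(traj.i >= 0.0)

    @pytest.mark.parametrize("mode", ["semelparous", "iteroparous"])
    def test_strain_exchange_symmetry(self, mode):
        """Two identical strains at half density reproduce the single-strain
        run when summed (the delay system is linear in strain labels)."""
        p = ph.default_parameters(mode)
        ref = season(p, 2e6, 1e6, 1.31)
        split = season(p, 2e6, [5e5, 5e5], [1.31, 1.31])
        assert np.allclose(split.v.sum(axis=0), ref.v[0], rtol=1e-9)
        assert np.allclose(split.s, ref.s, rtol=1e-9)

    def test_host_accounting(self, semel_params):
        """Emerged hosts at T are exactly split between s, r and the latent
        cohort when all background mortalities are equal."""
        p = semel_params
        tau = 1.31
        traj = season(p, 1e6, 1e6, tau)
        t, dt = traj.time, traj.time[1] - traj.time[0]
        mu = p.mu_s
        flux = p.beta * traj.s * traj.v[0]
        in_window = t > p.T - tau  # infections still latent at T
        latent = np.trapezoid(
            np.where(in_window, flux * np.exp(-mu * (p.T - t)), 0.0), t
        )
        total = traj.s[-1] + traj.r[-1] + latent
        expected = 1e6 * ph.disease_free_cohort_factor(p)
        assert total == pytest.approx(expected, rel=1e-3)

    def test_input_validation(self, semel_params):
        with pytest.raises(ValueError):
            season(semel_params, 1e6, [1.0, 2.0], [1.0])  # length mismatch
        with pytest.raises(ValueError):
            season(semel_params, 1e6, 1.0, -0.5)  # negative latency
        with pytest.raises(ValueError):
            ph.SeasonState(0, -1.0, np.array([1.0]))


class TestNumericalConvergence:
    @pytest.mark.parametrize("mode", ["semelparous", "iteroparous"])
    def test_step_refinement(self, mode):
        """Halving the RK4 step changes v(T) by far less than 0.1%."""
        p = ph.default_parameters(mode)
        coarse = season(p, 2e6, 1e6, 1.31, step=1e-3)
        fine = season(p, 2e6, 1e6, 1.31, step=5e-4)
        assert fine.v[0, -1] == pytest.approx(coarse.v[0, -1], rel=1e-3)

    def test_against_euler_oracle(self, semel_params):
        """Independent fixed-step explicit-Euler integration of the same
        delay system agrees with the RK4 method-of-steps solution."""
        p = semel_params
        tau, s_hat, v0, h = 1.31, 1e6, 1e6, 1e-4
        n, d = int(round(p.T / h)), int(round(tau / h))
        alpha = alpha_of_tau(tau, p)
        surv = np.exp(-p.mu_latent * tau)
        s = np.zeros(n + 1)
        v = np.zeros(n + 1)
        v[0] = v0
        for j in range(n):
            t = j * h
            g = 1.0 / p.tl if t < p.tl else 0.0
            P = s[j - d] * v[j - d] if j - d >= 0 else 0.0
            s[j + 1] = s[j] + h * (s_hat * g - p.mu_s * s[j] - p.beta * s[j] * v[j])
            v[j + 1] = v[j] + h * (
                p.beta * alpha * surv * P - p.delta * v[j] - p.beta * s[j] * v[j]
            )
        traj = season(p, s_hat, v0, tau)
        assert traj.v[0, -1] == pytest.approx(v[-1], rel=5e-3)
        assert traj.s[-1] == pytest.approx(s[-1], rel=5e-3)

    def test_against_desolve_oracle(self, tmp_path):
        """Cross-check one iteroparous season against R deSolve's dede
        solver (an entirely independent DDE implementation)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the deSolve cross-check")
        script = tmp_path / "season.R"
        script.write_text(
            textwrap.dedent(
                """
                library(deSolve)
                parms <- c(shat=1e6, tl=1, beta=1e-7, mus=0.25, mui=0.25,
                           mur=0.25, gamma=3, delta=1, tau=1.0,
                           alpha=200*(1.5)^0.8)
                deriv <- function(t, y, p) {
                  with(as.list(c(y, p)), {
                    g <- if (t <= tl) 1/tl else 0
                    P <- if (t > tau) { lag <- lagvalue(t - tau); lag[1]*lag[4] } else 0
                    list(c(shat*g - mus*s - beta*s*v,
                           beta*exp(-mus*tau)*P - (mui+gamma)*i,
                           gamma*i - mur*r,
                           alpha*i - delta*v - beta*s*v))
                  })
                }
                out <- dede(c(s=0, i=0, r=0, v=1e5), seq(0, 4, by=0.01), deriv,
                            parms, atol=1e-8, rtol=1e-10, hmax=0.01)
                last <- out[nrow(out),]
                cat(sprintf("%.10e %.10e %.10e %.10e", last["s"], last["i"],
                            last["r"], last["v"]))
                """
            )
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        s_R, i_R, r_R, v_R = map(float, res.stdout.split())
        p = ph.default_parameters("iteroparous")
        traj = season(p, 1e6, 1e5, 1.0)
        assert traj.s[-1] == pytest.approx(s_R, rel=1e-4)
        assert traj.i[0, -1] == pytest.approx(i_R, rel=1e-4)
        assert traj.r[-1] == pytest.approx(r_R, rel=1e-4)
        assert traj.v[0, -1] == pytest.approx(v_R, rel=1e-4)


class TestGenerationCounting:
    def test_no_parasites_no_generations(self, semel_params):
        traj = season(semel_params, 1e7, 0.0, 1.0)
        assert ph.infection_generation_count(traj) == 0

    def test_latency_beyond_season(self, semel_params):
        traj = season(semel_params, 1e7, 1e6, 4.5)
        assert ph.infection_generation_count(traj) == 0


class TestExport:
    def test_tidy_frame(self, itero_params):
        traj = season(itero_params, 1e6, [1e4, 2e4], [0.9, 2.4])
        df = traj.to_frame()
        assert set(df.columns) == {"time", "compartment", "strain_id", "density"}
        assert set(df["compartment"]) == {"s", "r", "v", "i"}
        assert (df["density"] >= 0).all()
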