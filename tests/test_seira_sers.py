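"""Enhancement machinery: induced dipole, local fields, EF statistics."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import plasmovib as pv
from plasmovib.molecule import (
    MolecularSurrogate,
    face_on_placement,
    gas_ir_intensities,
    gas_raman_activities,
    make_fixture,
    place,
    raman_invariants,
)
from plasmovib.response import SubstrateModel
from plasmovib.seira_sers import (
    _displaced,
    average_reports,
    dressed_dipole_derivative,
    dressed_raman_tensor,
    enhancement_report,
    induced_external_dipole,
    local_field_tensor,
    molecular_sources,
    probe_projected_dipole,
    seira_intensities,
    sers_intensities,
)
from plasmovib.units import bohr_to_angstrom, ev_to_cm


@pytest.fixture(scope="module")
def disk_system():
    disk = pv.build_graphene_disk(3.0)
    mol = make_fixture(11, n_atoms=10)
    placed = place(mol, disk, face_on_placement(mol, disk, 3.5))
    model = SubstrateModel(disk, pv.materials.graphene(0.4), mode="wfq")
    return placed, model


def point_dipole_molecule(point, mvec):
    return MolecularSurrogate(
        positions=np.asarray(point, float)[None, :], masses=[12.0], charges=[0.0],
        apt=np.zeros((1, 3, 3)), freqs_cm=[1000.0], modes_mw=np.eye(3)[:, :1],
        alpha_deriv=np.zeros((1, 3, 3)), dipoles=np.asarray(mvec, float)[None, :],
    )


class TestMolecularSources:
    def test_neutral_zero_source(self, disk_system):
        placed, model = disk_system
        mol = replace(placed, charges=np.zeros(placed.n_atoms), dipoles=None)
        src = molecular_sources(mol, model)
        assert np.all(src.potential == 0) and np.all(src.field == 0)

    def test_bare_coulomb_far_field(self, graphene_params):
        sub = pv.NanoStructure(np.zeros((1, 3)), np.array(["C"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SubstrateModel(sub, graphene_params, mode="wfq")
        mol = MolecularSurrogate(
            positions=bohr_to_angstrom(np.array([[0, 0, 50.0]])), masses=[1.0],
            charges=[1.0], apt=np.zeros((1, 3, 3)), freqs_cm=[500.0],
            modes_mw=np.eye(3)[:, :1], alpha_deriv=np.zeros((1, 3, 3)),
        )
        src = molecular_sources(mol, model)
        assert src.potential[0].real == pytest.approx(1.0 / 50.0, abs=1e-8)
        assert np.linalg.norm(src.field[0]) == pytest.approx(1.0 / 2500.0, abs=1e-8)

    def test_neutral_pair_dipole_decay(self, graphene_params):
        """Far-field potential of a ±q pair decays as r⁻² (log–log slope)."""
        sub = pv.NanoStructure(np.zeros((1, 3)), np.array(["C"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SubstrateModel(sub, graphene_params, mode="wfq")
        ds, vs = [], []
        for dist in [50.0, 80.0, 120.0, 200.0]:
            mol = MolecularSurrogate(
                positions=bohr_to_angstrom(
                    np.array([[0, 0, dist], [0, 0, dist + 1.5]])),
                masses=[1.0, 1.0], charges=[0.5, -0.5], apt=np.zeros((2, 3, 3)),
                freqs_cm=[500.0],
                modes_mw=np.linalg.qr(
                    np.random.default_rng(0).standard_normal((6, 1)))[0],
                alpha_deriv=np.zeros((1, 3, 3)),
            )
            src = molecular_sources(mol, model)
            ds.append(dist)
            vs.append(abs(src.potential[0]))
        slope = np.polyfit(np.log(ds), np.log(vs), 1)[0]
        assert slope == pytest.approx(-2.0, rel=0.02)

    def test_clash_rejected(self, disk_system):
        placed, model = disk_system
        too_close = replace(placed, positions=placed.positions - [0, 0, 2.8])
        with pytest.raises(ValueError, match="regularization"):
            molecular_sources(too_close, model)


class TestInducedDipole:
    def test_probe_projection_identity(self, disk_system):
        """Projecting the solution on three orthogonal uniform probes
        reproduces Σ(q_p·r_p + μ_p) componentwise."""
        placed, model = disk_system
        ind = induced_external_dipole(placed, model, 0.15)
        proj = probe_projected_dipole(ind.source_solution)
        assert np.abs(ind.value - proj).max() < 1e-10 * np.abs(ind.value).max()

    def test_linear_in_molecular_charges(self, disk_system):
        placed, model = disk_system
        d1 = induced_external_dipole(placed, model, 0.15).value
        doubled = replace(placed, charges=2 * placed.charges, total_charge=0.0)
        d2 = induced_external_dipole(doubled, model, 0.15).value
        assert np.abs(d2 - 2 * d1).max() < 1e-10 * np.abs(d1).max()

    @pytest.mark.parametrize("mode", ["wfq", "wfqfmu"])
    def test_reciprocity_with_local_field_dressing(self, mode, ico55):
        """Induced-dipole route equals dressing the transition dipole with
        the transposed local-field tensor (electromagnetic reciprocity)."""
        params = pv.materials.gold() if mode == "wfqfmu" else pv.materials.drude_gold()
        model = SubstrateModel(ico55, params, mode=mode)
        point = np.array([0.0, 0.0, ico55.positions[:, 2].max() + 4.0])
        mvec = np.array([0.3, -0.2, 0.7])
        mol = point_dipole_molecule(point, mvec)
        d1 = induced_external_dipole(mol, model, 2.0).value
        lam = local_field_tensor(model, point, 2.0)
        d2 = (lam - np.eye(3)).T @ mvec
        assert np.abs(d1 - d2).max() / np.abs(d1).max() < 1e-6


class TestLocalFieldTensor:
    def test_no_substrate_identity(self):
        lam = local_field_tensor(None, np.zeros(3), 2.0)
        assert np.allclose(lam, np.eye(3))

    def test_far_point_identity(self, ico55, drude_params):
        model = SubstrateModel(ico55, drude_params, mode="wfq")
        lam = local_field_tensor(model, np.array([0, 0, 5e3]), 2.0)
        assert np.abs(lam - np.eye(3)).max() < 1e-6

    def test_gradient_consistency(self, ico55, drude_params):
        """Λ from the scattered-field kernel equals the finite difference of
        the total potential at the same point."""
        from plasmovib.response import scattered_field_at, solve_wfq, uniform_field_source
        from plasmovib.units import angstrom_to_bohr

        model = SubstrateModel(ico55, drude_params, mode="wfq")
        point = np.array([2.0, -1.0, ico55.positions[:, 2].max() + 5.0])
        sol = solve_wfq(model, 2.0, uniform_field_source(ico55, [0, 0, 1]))
        _, E = scattered_field_at(sol, point[None, :])
        h = 1e-3  # Å
        num = np.zeros(3, dtype=complex)
        for b in range(3):
            for sgn in (1, -1):
                p = point.copy()
                p[b] += sgn * h
                V, _ = scattered_field_at(sol, p[None, :])
                num[b] += sgn * V[0] / (2 * h * angstrom_to_bohr(1.0))
        assert np.abs(E[0] + num).max() < 1e-6 * np.abs(E[0]).max()


class TestSeira:
    def test_no_substrate_reduces_to_gas(self, small_molecule):
        I, rep = seira_intensities(small_molecule, None)
        assert np.allclose(I, gas_ir_intensities(small_molecule))
        assert np.nanmax(np.abs(rep.ef - 1.0)) == 0.0
        assert rep.aef == 1.0 and rep.mef == 1.0

    def test_analytic_vs_numeric_dipole_derivative(self, small_molecule):
        """The APT route equals the 3-point numerical derivative of the
        surrogate dipole with the 0.001 Bohr step."""
        mol = small_molecule
        Lc = mol.cartesian_modes()
        for i in (0, mol.n_modes - 1):
            norm = np.linalg.norm(Lc[i])
            u = Lc[i] / norm
            num = (
                (_displaced(mol, u, 0.001).dipole()
                 - _displaced(mol, u, -0.001).dipole()) / 0.002 * norm
            )
            ana = np.einsum("nab,nb->a", mol.apt, Lc[i])
            assert np.abs(num - ana).max() < 1e-8 * max(np.abs(ana).max(), 1e-12)

    def test_half_step_stability(self, disk_system):
        """Halving the differentiation step (0.0005 Bohr) leaves the
        intensities essentially unchanged."""
        placed, model = disk_system
        I1, _ = seira_intensities(placed, model, step_bohr=0.001)
        I2, _ = seira_intensities(placed, model, step_bohr=0.0005)
        assert np.abs(I1 - I2).max() / I1.max() < 1e-4

    def test_imef_tracks_prf(self, disk_system):
        """Tuning the Fermi energy so the plasmon crosses the molecular mode
        window makes the most-enhanced mode follow the plasmon frequency."""
        placed, model = disk_system
        disk = model.structure
        for ef in (0.002, 0.0035):
            m = SubstrateModel(disk, pv.materials.graphene(ef), mode="wfq",
                               kbar=model.kbar)
            spec = pv.absorption_spectrum(m, np.arange(0.04, 0.40, 0.004))
            prf_cm = ev_to_cm(spec.prf_ev)
            assert 550.0 < prf_cm < 1700.0  # inside the mode window
            _, rep = seira_intensities(placed, m)
            assert abs(rep.freqs_cm[rep.i_mef] - prf_cm) <= 150.0


class TestSers:
    def test_no_substrate_reduces_to_gas(self, small_molecule):
        I, rep = sers_intensities(small_molecule, None, omega_inc_ev=2.2)
        assert np.allclose(I, gas_raman_activities(small_molecule))
        assert rep.aef == 1.0 and rep.mef == 1.0

    def test_scalar_isotropic_quartic_vs_quadratic(self):
        """With Λ = λ·I and isotropic tensors, EF_SERS = |λ|⁴ = EF_SEIRA²."""
        lam = (1.2 - 0.9j) * np.eye(3)
        a_iso = 1.7 * np.eye(3)
        ddq = np.array([0.4, -0.1, 0.2])
        a2, g2 = raman_invariants(dressed_raman_tensor(a_iso, lam)[None])
        ef_sers = (45 * a2[0] + 7 * g2[0]) / (45 * 1.7**2)
        ef_seira = (
            np.sum(np.abs(dressed_dipole_derivative(ddq, lam)) ** 2)
            / np.sum(ddq**2)
        )
        assert ef_sers == pytest.approx(abs(1.2 - 0.9j) ** 4, rel=1e-10)
        assert ef_sers == pytest.approx(ef_seira**2, rel=1e-6)

    def test_rotation_covariance(self, disk_system):
        """Rotating molecule and substrate together leaves EFs unchanged."""
        placed, model = disk_system
        I0, rep0 = sers_intensities(placed, model, omega_inc_ev=1.0)
        th = 0.7
        R = np.array([
            [np.cos(th), -np.sin(th), 0.0],
            [np.sin(th), np.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ])
        sub_rot = pv.NanoStructure(model.structure.positions @ R.T,
                                   model.structure.labels)
        model_rot = SubstrateModel(sub_rot, model.params, mode="wfq")
        mol_rot = placed.transformed(rotation=R)
        I1, rep1 = sers_intensities(mol_rot, model_rot, omega_inc_ev=1.0)
        assert np.abs(I1 - I0).max() / I0.max() < 1e-6
        assert rep1.aef == pytest.approx(rep0.aef, rel=1e-6)


class TestEnhancementReport:
    def test_worked_example(self):
        r = enhancement_report([100.0, 200.0], [2.0, 4.0], [1.0, 1.0])
        assert np.allclose(r.ef, [2.0, 4.0])
        assert r.aef == 3.0 and r.mef == 4.0 and r.i_mef == 1

    def test_identical_lists_unity(self):
        r = enhancement_report([1.0, 2.0, 3.0], [5.0, 1.0, 2.0], [5.0, 1.0, 2.0])
        assert np.allclose(r.ef, 1.0) and r.aef == 1.0 and r.mef == 1.0

    def test_zero_vac_mode_excluded_from_mef(self):
        r = enhancement_report([1.0, 2.0], [100.0, 4.0], [0.0, 2.0])
        assert np.isnan(r.ef[0]) and r.mef == 2.0
        assert r.aef == pytest.approx(104.0 / 2.0)

    def test_mef_dominates_aef_random(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            I = rng.uniform(0.1, 10.0, 6)
            Iv = rng.uniform(0.1, 10.0, 6)
            r = enhancement_report(np.arange(6.0), I, Iv)
            assert r.mef >= r.aef - 1e-12

    def test_all_zero_vacuum_rejected(self):
        with pytest.raises(ZeroDivisionError):
            enhancement_report([1.0], [1.0], [0.0])

    def test_tie_breaks_to_lowest_frequency(self):
        r = enhancement_report([300.0, 100.0, 200.0], [2.0, 2.0, 1.0],
                               [1.0, 1.0, 1.0])
        assert r.freqs_cm[r.i_mef] == 100.0


class TestAveraging:
    def test_single_report_identity(self):
        r = enhancement_report([1.0, 2.0], [2.0, 4.0], [1.0, 1.0])
        avg = average_reports([r])
        assert np.allclose(avg.intensities, r.intensities)

    def test_mean_of_two(self):
        r1 = enhancement_report([1.0, 2.0], [0.0, 2.0], [1.0, 1.0])
        r2 = enhancement_report([1.0, 2.0], [2.0, 0.0], [1.0, 1.0])
        avg = average_reports([r1, r2])
        assert np.allclose(avg.intensities, [1.0, 1.0])

    def test_mismatched_modes_rejected(self):
        r1 = enhancement_report([1.0, 2.0], [1.0, 2.0], [1.0, 1.0])
        r2 = enhancement_report([1.0, 3.0], [1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            average_reports([r1, r2])
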