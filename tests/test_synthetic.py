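"""Synthetic duplex generator: builder geometry, lesions, bends, kinetics."""

import numpy as np
import pytest

import ncpdyn as nd
from conftest import SEQ15


class TestBuildBdna:
    def test_two_mer_complementarity(self):
        s = nd.build_bdna(nd.SynthConfig(sequence="AT"))
        chains = s.chains
        assert chains == {"A": [1, 2], "B": [1, 2]}
        res = {(c, r): str(s.res_name[s.residue_atom_indices(c, r)[0]])
               for c in "AB" for r in (1, 2)}
        # A:1 (DA) pairs B:2 (DT); A:2 (DT) pairs B:1 (DA)
        assert res == {("A", 1): "DA", ("A", 2): "DT",
                       ("B", 1): "DA", ("B", 2): "DT"}

    def test_rise_between_pair_centers(self, duplex15):
        def center(k):
            a = nd.select_atoms(duplex15, chain="A", residue_number=k,
                                atom_name="C1'")
            b = nd.select_atoms(duplex15, chain="B", residue_number=16 - k,
                                atom_name="C1'")
            return 0.5 * (duplex15.coords[a[0]] + duplex15.coords[b[0]])
        for k in range(1, 15):
            step = center(k + 1) - center(k)
            assert np.linalg.norm(step) == pytest.approx(3.38, abs=1e-6)

    def test_c1p_c1p_across_every_pair(self, duplex15):
        for k in range(1, 16):
            a = nd.select_atoms(duplex15, chain="A", residue_number=k,
                                atom_name="C1'")
            b = nd.select_atoms(duplex15, chain="B", residue_number=16 - k,
                                atom_name="C1'")
            d = np.linalg.norm(duplex15.coords[a[0]] - duplex15.coords[b[0]])
            assert 10.0 <= d <= 11.0

    def test_non_acgt_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            nd.SynthConfig(sequence="AXT")

    def test_alternating_tetramer_helper(self):
        seq = nd.alternating_tetramer_sequence(10)
        assert seq == "GCGCATATGC"


class TestApplyLesion:
    def test_ap_lesion_postconditions(self, lesioned15, site15):
        chain, resnum = site15.lesion
        base = nd.select_atoms(lesioned15, chain=chain,
                               residue_number=resnum, base_only=True)
        assert base.size == 0
        c1 = nd.select_atoms(lesioned15, chain=chain, residue_number=resnum,
                             atom_name="C1'")
        assert c1.size == 1
        assert str(lesioned15.res_name[
            lesioned15.residue_atom_indices(chain, resnum)[0]]) == "AP"

    def test_ap_vs_thf_differ_only_by_o1p(self, duplex15, site15):
        ap = nd.apply_lesion(duplex15, site15.lesion, "AP")
        thf = nd.apply_lesion(duplex15, site15.lesion, "THF")
        chain, resnum = site15.lesion
        ap_names = set(ap.name[ap.residue_atom_indices(chain, resnum)])
        thf_names = set(thf.name[thf.residue_atom_indices(chain, resnum)])
        assert ap_names - thf_names == {"O1'"}
        assert thf_names <= ap_names

    def test_atom_count_drop_matches_template_base(self, duplex15, site15):
        chain, resnum = site15.lesion
        n_base = nd.select_atoms(duplex15, chain=chain,
                                 residue_number=resnum, base_only=True).size
        assert n_base == 10  # adenine heavy base atoms
        thf = nd.apply_lesion(duplex15, site15.lesion, "THF")
        assert duplex15.n_atoms - thf.n_atoms == n_base
        ap = nd.apply_lesion(duplex15, site15.lesion, "AP")
        assert duplex15.n_atoms - ap.n_atoms == n_base - 1  # O1' added back

    def test_double_lesion_is_an_error(self, lesioned15, site15):
        with pytest.raises(ValueError, match="already abasic"):
            nd.apply_lesion(lesioned15, site15.lesion, "THF")


class TestBendArc:
    def test_angle_zero_is_identity(self, duplex15):
        bent = nd.bend_arc(duplex15, 0.0)
        np.testing.assert_array_equal(bent.coords, duplex15.coords)

    def test_out_of_range_angle(self, duplex15):
        with pytest.raises(ValueError):
            nd.bend_arc(duplex15, 180.0)
        with pytest.raises(ValueError):
            nd.bend_arc(duplex15, -5.0)

    def test_within_pair_com_distances_preserved(self, duplex15):
        bent = nd.bend_arc(duplex15, 55.0)
        for traj_s, tag in ((duplex15, "straight"), (bent, "bent")):
            traj = nd.Trajectory(traj_s, traj_s.coords[None])
            d = nd.com_distance_series(traj, ("A", 5), ("B", 11)).values[0]
            if tag == "straight":
                ref = d
        assert d == pytest.approx(ref, abs=1e-9)


class TestFlipDynamics:
    def test_absorbing_intrahelical_state(self, lesioned15, site15):
        traj, labels = nd.simulate_flip_dynamics(
            lesioned15, [nd.FlipSpec(site=site15.lesion, p_out=0.0,
                                     p_in=0.5)], 200, seed=1)
        assert (labels.state == "intra").all()
        series = nd.c1p_distance_series(traj, site15)
        assert nd.extrahelicity_percent(series) == 0.0

    def test_exact_fraction_count_and_spacing(self, lesioned15, site15):
        states = nd.simulate_states(
            [nd.FlipSpec(site=site15.lesion, mode="exact_fraction",
                         fraction=0.5)], 10, seed=0)[site15.lesion]
        assert states.sum() == 5
        # placement is evenly spaced, not a consecutive block
        runs = np.diff(np.flatnonzero(states))
        assert np.all(runs == 2)

    def test_exact_fraction_requires_fraction(self, site15):
        with pytest.raises(ValueError, match="fraction"):
            nd.FlipSpec(site=site15.lesion, mode="exact_fraction")

    def test_unknown_coupling_site_errors(self, lesioned15, site15):
        flips = [nd.FlipSpec(site=site15.lesion, couple_to=("B", 99))]
        with pytest.raises(ValueError, match="unknown site"):
            nd.simulate_states(flips, 10, seed=0)

    def test_seed_reproducibility_bit_for_bit(self, lesioned15, site15):
        flips = [nd.FlipSpec(site=site15.lesion, p_out=0.1, p_in=0.2)]
        t1, l1 = nd.simulate_flip_dynamics(lesioned15, flips, 50, seed=11,
                                           noise_sigma=0.2)
        t2, l2 = nd.simulate_flip_dynamics(lesioned15, flips, 50, seed=11,
                                           noise_sigma=0.2)
        np.testing.assert_array_equal(t1.frames, t2.frames)
        assert l1.equals(l2)

    def test_seed_changes_noise_not_designed_counts(self, lesioned15, site15):
        flips = [nd.FlipSpec(site=site15.lesion, mode="exact_fraction",
                             fraction=0.3)]
        t1, l1 = nd.simulate_flip_dynamics(lesioned15, flips, 100, seed=1,
                                           noise_sigma=0.1)
        t2, l2 = nd.simulate_flip_dynamics(lesioned15, flips, 100, seed=2,
                                           noise_sigma=0.1)
        assert not np.array_equal(t1.frames, t2.frames)
        assert (l1.state == "extra").sum() == (l2.state == "extra").sum() == 30

    def test_ground_truth_matches_threshold_classifier(self, lesioned15,
                                                       site15):
        # templates cross the 14 Å threshold by >= 2 Å; noise 0.3 Å
        traj, labels = nd.simulate_flip_dynamics(
            lesioned15,
            [nd.FlipSpec(site=site15.lesion, mode="exact_fraction",
                         fraction=0.4)],
            1000, seed=7, noise_sigma=0.3)
        series = nd.c1p_distance_series(traj, site15)
        pred = series.values > 14.0
        truth = (labels.state == "extra").to_numpy()
        assert (pred == truth).mean() >= 0.99


class TestTailProbe:
    @pytest.fixture()
    def base_traj(self, lesioned15):
        return nd.Trajectory(lesioned15,
                             np.repeat(lesioned15.coords[None], 50, axis=0))

    def test_always_in_contact(self, base_traj, lesioned15, site15):
        script = nd.ContactScript(episodes=[(0, 50, 3.0)])
        site = nd.site_heavy_atoms(lesioned15, site15.lesion)
        probed = nd.add_tail_probe(base_traj, script, site)
        groups = nd.find_charged_groups(probed.topology, ["P"])
        nz = [g for g in groups if g.group_kind == "LYS_NZ"][0]
        assert nd.residence_frequency(probed, nz, site, 6.0) == 100.0

    def test_never_in_contact(self, base_traj, lesioned15, site15):
        script = nd.ContactScript(episodes=[], off_distance=20.0)
        site = nd.site_heavy_atoms(lesioned15, site15.lesion)
        probed = nd.add_tail_probe(base_traj, script, site)
        nz = [g for g in nd.find_charged_groups(probed.topology, ["P"])
              if g.group_kind == "LYS_NZ"][0]
        assert nd.residence_frequency(probed, nz, site, 6.0) == 0.0

    def test_scripted_distance_is_exact_minimum(self, base_traj, lesioned15,
                                                site15):
        from ncpdyn.contacts import min_distance_series
        script = nd.ContactScript(episodes=[(10, 20, 4.0)])
        site = nd.site_heavy_atoms(lesioned15, site15.lesion)
        probed = nd.add_tail_probe(base_traj, script, site)
        nz = [g for g in nd.find_charged_groups(probed.topology, ["P"])
              if g.group_kind == "LYS_NZ"][0]
        dmin = min_distance_series(probed, np.array(nz.atom_indices), site)
        np.testing.assert_allclose(dmin[10:20], 4.0, atol=1e-9)
        np.testing.assert_allclose(dmin[:10], 20.0, atol=1e-9)

    def test_target_beyond_off_distance_rejected(self, base_traj, lesioned15,
                                                 site15):
        script = nd.ContactScript(episodes=[(0, 5, 25.0)], off_distance=20.0)
        site = nd.site_heavy_atoms(lesioned15, site15.lesion)
        with pytest.raises(ValueError, match="off_distance"):
            nd.add_tail_probe(base_traj, script, site)
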