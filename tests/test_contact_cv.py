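import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactfes.contact_cv import (
    ContactSet,
    ContactSpec,
    build_contact_set,
    cv_gradient,
    cv_pair,
    cv_trajectory,
    read_colvar,
    read_contacts,
    switching_value,
    write_colvar,
    write_contacts,
)
from contactfes.errors import ConsistencyError, ResidueLookupError
from contactfes.structio import Atom, Structure, Trajectory
from contactfes.synthetic import make_two_state_references, random_two_state_spec


class TestSwitchingFunction:
    def test_limit_at_reference_distance(self):
        # removable singularity: (1-x^6)/(1-x^10) -> 6/10 as x -> 1
        assert switching_value(4.0, 4.0) == pytest.approx(0.6, abs=1e-12)

    def test_short_distance_asymptote_is_the_weight(self):
        assert switching_value(1e-9, 4.0, weight=3.0) == pytest.approx(3.0)

    def test_closed_form_at_twice_r0(self):
        # (1 - 2^6)/(1 - 2^10) = 63/1023
        assert switching_value(8.0, 4.0) == pytest.approx(63.0 / 1023.0,
                                                          rel=1e-12)

    def test_continuity_across_the_singularity(self):
        r0 = 4.0
        vals = switching_value(r0 * (1 + np.array([-1e-5, -1e-7, 0, 1e-7, 1e-5])),
                               r0)
        assert np.all(np.abs(vals - 0.6) < 1e-4)
        assert np.all(np.diff(vals) < 0)

    @given(st.floats(min_value=0.01, max_value=30.0),
           st.floats(min_value=0.02, max_value=30.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strictly_decreasing_and_bounded(self, r1, r2):
        lo, hi = sorted([r1, r2])
        v_lo, v_hi = switching_value(np.array([lo, hi]), 5.0)
        assert 0 < v_hi <= 1.0 and 0 < v_lo <= 1.0
        if hi - lo > 1e-9:
            assert v_lo > v_hi

    def test_bad_r0_rejected(self):
        with pytest.raises(ValueError):
            switching_value(1.0, -1.0)


def _two_contact_structures():
    """Two contacts, r0 = 4 Å; references realize both at exactly r0."""
    def atoms(d1, d2):
        return [
            Atom(1, "CB", "ALA", 1, "A", np.array([0.0, 0.0, 0.0])),
            Atom(2, "CB", "ALA", 2, "A", np.array([d1, 0.0, 0.0])),
            Atom(3, "CB", "ALA", 3, "A", np.array([0.0, 50.0, 0.0])),
            Atom(4, "CB", "ALA", 4, "A", np.array([d2, 50.0, 0.0])),
        ]
    ref = Structure(atoms(4.0, 4.0))
    probe = Structure(atoms(4.0, 8.0))
    contacts = [
        ContactSpec(("A", 1, "CB"), ("A", 2, "CB"), r0=4.0),
        ContactSpec(("A", 3, "CB"), ("A", 4, "CB"), r0=4.0),
    ]
    cs = ContactSet.from_contacts(contacts, ref, ref)
    return cs, ref, probe


class TestCVPair:
    def test_zero_at_own_reference(self, two_state, contact_set):
        cv1, cv2 = cv_pair(two_state["ref_in"], contact_set)
        assert cv1 == pytest.approx(0.0, abs=1e-15)
        assert cv2 > 0

    def test_hand_computed_two_contact_example(self):
        cs, ref, probe = _two_contact_structures()
        cv1, cv2 = cv_pair(probe, cs)
        d_far = 63.0 / 1023.0
        expected = ((0.0) ** 2 + (d_far - 0.6) ** 2) / 2.0
        assert cv1 == pytest.approx(expected, rel=1e-12)
        assert cv1 == pytest.approx(0.144946, abs=5e-6)

    def test_mirror_identity_is_exact(self, two_state, contact_set):
        cv1_on_active, _ = cv_pair(two_state["ref_ac"], contact_set)
        _, cv2_on_inactive = cv_pair(two_state["ref_in"], contact_set)
        assert cv1_on_active == cv2_on_inactive

    def test_bounded_in_unit_interval(self, two_state, contact_set, rng):
        for _ in range(20):
            coords = two_state["ref_in"].coords + 3.0 * rng.normal(
                size=two_state["ref_in"].coords.shape)
            cv1, cv2 = cv_pair(coords, contact_set,
                               indices=contact_set.resolve_indices(
                                   two_state["ref_in"]))
            assert 0.0 <= cv1 <= 1.0 and 0.0 <= cv2 <= 1.0

    def test_matches_naive_double_loop_oracle(self, two_state, contact_set, rng):
        """The vectorized CV equals a per-contact scalar re-implementation."""
        ref = two_state["ref_in"]
        idx = contact_set.resolve_indices(ref)
        for _ in range(25):
            coords = ref.coords + rng.normal(size=ref.coords.shape)
            cv1, cv2 = cv_pair(coords, contact_set, indices=idx)
            n = contact_set.normalization
            s1 = s2 = 0.0
            for k, c in enumerate(contact_set.contacts):
                ia, ib = idx[0][k], idx[1][k]
                r = float(np.linalg.norm(coords[ia] - coords[ib]))
                d = switching_value(r, c.r0, c.weight)
                s1 += (d - contact_set.d_ref_inactive[k]) ** 2
                s2 += (d - contact_set.d_ref_active[k]) ** 2
            assert cv1 == pytest.approx(s1 / n, abs=1e-10)
            assert cv2 == pytest.approx(s2 / n, abs=1e-10)

    def test_missing_atom_names_the_contact(self, contact_set):
        lonely = Structure([Atom(1, "CA", "ALA", 1, "Z", np.zeros(3))])
        with pytest.raises(ResidueLookupError, match="contact"):
            cv_pair(lonely, contact_set)


class TestCVGradient:
    def test_zero_at_own_reference(self, two_state, contact_set):
        g = cv_gradient(two_state["ref_in"], contact_set, "cv1")
        assert np.abs(g).max() < 1e-12

    def test_matches_central_finite_differences(self, two_state, contact_set,
                                                rng):
        ref = two_state["ref_in"]
        idx = contact_set.resolve_indices(ref)
        coords = ref.coords + 0.3 * rng.normal(size=ref.coords.shape)
        for which in ("cv1", "cv2"):
            g = cv_gradient(coords, contact_set, which, indices=idx)
            h = 1e-5
            probe_atoms = set(idx[0][:3]) | set(idx[1][:3]) | {0}
            for i in probe_atoms:
                for k in range(3):
                    cp = coords.copy()
                    cp[i, k] += h
                    up = cv_pair(cp, contact_set, indices=idx)
                    cp[i, k] -= 2 * h
                    dn = cv_pair(cp, contact_set, indices=idx)
                    sel = 0 if which == "cv1" else 1
                    fd = (up[sel] - dn[sel]) / (2 * h)
                    assert abs(fd - g[i, k]) < 1e-5

    def test_atoms_outside_gamma_have_zero_rows(self, two_state, contact_set):
        ref = two_state["ref_in"]
        idx = contact_set.resolve_indices(ref)
        in_gamma = set(idx[0]) | set(idx[1])
        g = cv_gradient(ref.coords + 0.1, contact_set, "cv1", indices=idx)
        for i in range(len(ref)):
            if i not in in_gamma:
                assert np.all(g[i] == 0.0)


class TestBuildContactSet:
    def test_recovers_planted_pairs_and_discards_common(self, two_state,
                                                        contact_set):
        man = two_state["manifest"]
        got = sorted(tuple(sorted([c.atom_a, c.atom_b]))
                     for c in contact_set.contacts)
        want = sorted(
            tuple(sorted([tuple(p[0]), tuple(p[1])]))
            for p in man["planted_inactive"] + man["planted_active"])
        assert got == want
        common = {tuple(sorted([tuple(p[0]), tuple(p[1])]))
                  for p in man["planted_common"]}
        assert not common & set(got)

    def test_specificity_labels_match_ground_truth(self, two_state,
                                                   contact_set):
        man = two_state["manifest"]
        truth = {}
        for p in man["planted_inactive"]:
            truth[tuple(sorted([tuple(p[0]), tuple(p[1])]))] = "inactive"
        for p in man["planted_active"]:
            truth[tuple(sorted([tuple(p[0]), tuple(p[1])]))] = "active"
        for c in contact_set.contacts:
            assert truth[tuple(sorted([c.atom_a, c.atom_b]))] == c.specificity

    def test_below_min_presence_is_discarded(self, two_state):
        # demand presence in more members than exist: nothing survives
        with pytest.raises(ValueError, match="empty"):
            build_contact_set(two_state["ens_in"], two_state["ens_ac"],
                              two_state["ref_in"], two_state["ref_ac"],
                              min_presence=len(two_state["ens_in"]) + 1)

    def test_invariant_under_ensemble_member_order(self, two_state):
        a = build_contact_set(two_state["ens_in"], two_state["ens_ac"],
                              two_state["ref_in"], two_state["ref_ac"])
        b = build_contact_set(two_state["ens_in"][::-1],
                              two_state["ens_ac"][::-1],
                              two_state["ref_in"], two_state["ref_ac"])
        assert [(c.atom_a, c.atom_b, c.r0, c.specificity) for c in a.contacts] \
            == [(c.atom_a, c.atom_b, c.r0, c.specificity) for c in b.contacts]

    def test_swapping_ensembles_swaps_specificity(self, two_state):
        swapped = build_contact_set(two_state["ens_ac"], two_state["ens_in"],
                                    two_state["ref_ac"], two_state["ref_in"])
        direct = build_contact_set(two_state["ens_in"], two_state["ens_ac"],
                                   two_state["ref_in"], two_state["ref_ac"])
        flip = {"inactive": "active", "active": "inactive"}
        d1 = {tuple(sorted([c.atom_a, c.atom_b])): c.specificity
              for c in direct.contacts}
        d2 = {tuple(sorted([c.atom_a, c.atom_b])): c.specificity
              for c in swapped.contacts}
        assert d2 == {k: flip[v] for k, v in d1.items()}

    def test_salt_bridges_appended_with_triple_weight(self, two_state):
        man = two_state["manifest"]
        pair = man["planted_common"][0]
        sb = [((tuple(pair[0]), tuple(pair[1])), "active")]
        cs = build_contact_set(two_state["ens_in"], two_state["ens_ac"],
                               two_state["ref_in"], two_state["ref_ac"],
                               salt_bridges=sb)
        assert cs.contacts[-1].weight == 3.0
        assert cs.normalization == pytest.approx(
            sum(c.weight**2 for c in cs.contacts))

    def test_mismatched_ensembles_rejected(self, two_state, toy_chain):
        with pytest.raises(ConsistencyError):
            build_contact_set([toy_chain], two_state["ens_ac"],
                              two_state["ref_in"], two_state["ref_ac"])


class TestClassificationProperty:
    def test_near_reference_frames_fall_in_their_corner(self, two_state,
                                                        contact_set, rng):
        """Frames generated near a reference satisfy the CV threshold that
        labels that conformation."""
        for ref, near_cv in ((two_state["ref_in"], 0), (two_state["ref_ac"], 1)):
            idx = contact_set.resolve_indices(ref)
            for _ in range(10):
                coords = ref.coords + 0.1 * rng.normal(size=ref.coords.shape)
                cv = cv_pair(coords, contact_set, indices=idx)
                assert cv[near_cv] < 0.2
                assert cv[1 - near_cv] > cv[near_cv]


class TestCVTrajectory:
    def test_reference_copies_give_zero_cv1(self, two_state, contact_set):
        ref = two_state["ref_in"]
        traj = Trajectory(ref, [ref.coords.copy() for _ in range(4)])
        recs = cv_trajectory(traj, contact_set)
        assert all(r.cv1 == pytest.approx(0.0, abs=1e-15) for r in recs)

    def test_matches_per_frame_cv_pair_and_stride(self, two_state,
                                                  contact_set, rng):
        ref = two_state["ref_in"]
        frames = [ref.coords + 0.2 * rng.normal(size=ref.coords.shape)
                  for _ in range(10)]
        traj = Trajectory(ref, frames)
        recs = cv_trajectory(traj, contact_set)
        idx = contact_set.resolve_indices(ref)
        for k, r in enumerate(recs):
            assert (r.cv1, r.cv2) == pytest.approx(
                cv_pair(frames[k], contact_set, indices=idx))
        assert len(cv_trajectory(traj, contact_set, stride=2)) == 5


class TestTextInterchange:
    def test_contact_file_bit_exact_roundtrip(self, contact_set, tmp_path):
        p = tmp_path / "contacts.tsv"
        write_contacts(contact_set.contacts, p)
        back = read_contacts(p)
        assert back == contact_set.contacts
        write_contacts(back, tmp_path / "c2.tsv")
        assert (tmp_path / "c2.tsv").read_text() == p.read_text()

    def test_colvar_roundtrip(self, tmp_path):
        from contactfes.contact_cv import CVRecord
        recs = [CVRecord(0.0, 0.1, 0.9), CVRecord(2.0, 0.25, 0.75)]
        p = tmp_path / "colvar"
        write_colvar(recs, p)
        assert p.read_text().startswith("#! FIELDS time cv1 cv2")
        back = read_colvar(p)
        assert [(r.time, r.cv1, r.cv2) for r in back] == pytest.approx(
            [(r.time, r.cv1, r.cv2) for r in recs])
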