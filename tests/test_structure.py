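import numpy as np
import pytest
from itertools import combinations
from scipy.spatial.distance import cdist

from nescan import sasa
from nescan import structure as strc
from nescan.structure import (
    SamplingConfig, ScaledBackend, SurrogateEnergy, aggregate_energy,
    build_template_library, e_bind, interface_rsa, optimize_rsa_weight,
    refine_models, rsa_correct, sample_models, thread_peptide,
)
from nescan.synthetic import match_from_registry

from conftest import make_ideal_peptide


def get_template(templates, template_id):
    return next(t for t in templates if t.template_id == template_id)


class TestTemplateLibrary:
    def test_synthetic_library_covers_required_classes(self, templates):
        assert len(templates) == 8
        classes = [t.class_id for t in templates]
        assert classes.count("1a") == 2 and classes.count("2") == 2
        for cid in strc.REQUIRED_TEMPLATE_CLASSES:
            assert cid in classes

    def test_pockets_lie_near_groove_residues(self, templates):
        for t in templates:
            d = cdist(t.pockets, t.groove.centroid).min(axis=1)
            assert (d <= 12.0).all()

    def test_phi_anchors_sit_over_their_pockets(self, templates):
        for t in templates:
            for slot, k in t.phi_slots.items():
                a = t.anchor_ca[t.registry[slot]]
                assert np.linalg.norm(a[:2] - t.pockets[k][:2]) < 1e-9

    def test_class_backbones_geometrically_distinct(self, templates):
        def spacer_rmsd(a, b):
            phi = set(a.phi_slots) | set(b.phi_slots)
            common = [o for o in a.slot_offsets
                      if o in b.registry and o not in phi and o > 0]
            A = np.array([a.anchor_ca[a.registry[o]] for o in common])
            B = np.array([b.anchor_ca[b.registry[o]] for o in common])
            return np.sqrt(((A - B) ** 2).sum(axis=1).mean())
        for a, b in combinations(templates, 2):
            if a.class_id != b.class_id:
                assert spacer_rmsd(a, b) >= 2.0

    def test_1a_and_1c_differ_by_one_step_in_phi2_phi3_spacing(self, templates):
        t1a = get_template(templates, "1a:6CIT")
        t1c = get_template(templates, "1c:3GB8")
        phi3_slot_1a = [o for o, k in t1a.phi_slots.items() if k == 3][0]
        phi3_slot_1c = [o for o, k in t1c.phi_slots.items() if k == 3][0]
        assert phi3_slot_1c - phi3_slot_1a == 1

    def test_manifest_missing_class_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("")
        with pytest.raises(Exception, match="missing classes"):
            build_template_library(tmp_path, tmp_path / "m.tsv")


class TestThreading:
    def test_peptide_length_equals_registry_window(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        model = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        assert len(model.aa) == match.seg_end - match.seg_start + 1

    def test_threading_is_deterministic(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        t = get_template(templates, "1a:6CIT")
        a, b = thread_peptide(seq, match, t), thread_peptide(seq, match, t)
        assert np.array_equal(a.ca, b.ca) and np.array_equal(a.centroid, b.centroid)

    def test_short_rev_window_threads_clipped(self, templates, table1_by_name):
        # the 13-residue HIV-Rev fragment on the rev-type class-2 template
        entry = table1_by_name["HIV_Rev"]
        match = match_from_registry(entry.sequence, "2", entry.phi_local)
        model = thread_peptide(entry.sequence, match,
                               get_template(templates, "2:3NBZ"))
        # the registry window (Φ0−1 … Φ4+2) is clipped at the 13-mer's ends
        assert len(model.aa) == match.seg_end - match.seg_start + 1
        assert len(model.aa) < len(entry.sequence)
        # threaded in the reverse template's frame: residues mirrored
        assert model.aa == entry.sequence[match.seg_start - 1:
                                          match.seg_end][::-1]

    def test_on_register_phi_centroids_reach_pockets(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        model = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        rows = np.where(model.phi_mask)[0]
        d = cdist(model.centroid[rows], model.template.pockets).min(axis=1)
        assert (d < 0.6).all()

    def test_mirrored_threading_puts_phis_off_pocket(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        model = thread_peptide(seq, match, get_template(templates, "1a-R:5DIF"))
        rows = np.where(model.phi_mask)[0]
        d = cdist(model.centroid[rows], model.template.pockets).min(axis=1)
        assert d.mean() > 2.0


class QuadraticBackend:
    """Toy convex energy for the Metropolis property check."""

    name = "quadratic"
    deterministic = True

    def evaluate(self, model):
        return float(np.sum((model.ca - model.anchor_ca) ** 2))


class TestSampling:
    def test_seeded_chains_are_bitwise_reproducible(self, templates, ideal_1a, backend):
        seq, phis, match = ideal_1a
        pose = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        a = sample_models(pose, backend, n_models=3, n_trials=30, seed=5)
        b = sample_models(pose, backend, n_models=3, n_trials=30, seed=5)
        assert len(a) == 3
        for x, y in zip(a, b):
            assert x.energy == y.energy and np.array_equal(x.ca, y.ca)

    def test_zero_trials_returns_input_pose(self, templates, ideal_1a, backend):
        seq, phis, match = ideal_1a
        pose = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        (model,) = sample_models(pose, backend, n_models=1, n_trials=0, seed=1)
        assert np.array_equal(model.ca, pose.ca)

    def test_metropolis_prefers_low_energy_states(self, templates, ideal_1a):
        # on a quadratic landscape the chain's stationary energies must sit
        # well below those of blind proposals from the same move kernel
        seq, phis, match = ideal_1a
        pose = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        backend = QuadraticBackend()
        chains = sample_models(pose, backend, n_models=20, n_trials=400, seed=9)
        chain_mean = np.mean([m.energy for m in chains])
        rng = np.random.default_rng(9)
        blind = []
        for _ in range(20):
            model = pose.copy()
            for _ in range(400):
                r = int(rng.integers(len(model.aa)))
                model.ca[r] += rng.normal(0.0, 0.15, 3)
            blind.append(backend.evaluate(model))
        assert chain_mean < np.mean(blind)


class TestRefinement:
    def _samples(self, templates, ideal_1a, backend):
        seq, phis, match = ideal_1a
        pose = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        return sample_models(pose, backend, n_models=6, n_trials=25, seed=2)

    def test_children_never_worse_than_parents(self, templates, ideal_1a, backend):
        samples = self._samples(templates, ideal_1a, backend)
        parents = sorted(samples, key=lambda m: m.energy)[:3]
        children = refine_models(samples, backend, n_relax=4, seed=3,
                                 n_parents=3, relax_steps=10)
        worst_parent = max(p.energy for p in parents)
        assert len(children) == 12
        assert all(c.energy <= worst_parent + 1e-12 for c in children)

    def test_single_relax_run_yields_one_child_per_parent(self, templates, ideal_1a, backend):
        samples = self._samples(templates, ideal_1a, backend)
        children = refine_models(samples, backend, n_relax=1, seed=3,
                                 n_parents=5, relax_steps=5)
        assert len(children) == 5

    def test_children_stay_within_constraint_radius(self, templates, ideal_1a, backend):
        samples = self._samples(templates, ideal_1a, backend)
        parents = sorted(samples, key=lambda m: m.energy)[:2]
        children = refine_models(samples, backend, n_relax=3, seed=4,
                                 n_parents=2, relax_steps=20,
                                 constraint_radius=0.5)
        for i, c in enumerate(children):
            p = parents[i // 3]
            assert np.linalg.norm(c.ca - p.ca, axis=1).max() <= 0.5 + 1e-9


class TestAggregateEnergy:
    def test_mean_of_ten_lowest(self):
        assert aggregate_energy(list(range(1, 501)), k=10) == 5.5

    def test_constant_energies(self):
        assert aggregate_energy([3.25] * 40, k=10) == 3.25

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.normal(size=rng.integers(10, 80)).tolist()
            k = int(rng.integers(1, 10))
            oracle = sum(sorted(vals)[:k]) / k
            assert aggregate_energy(vals, k) == pytest.approx(oracle)

    def test_fewer_than_k_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="using all"):
            assert aggregate_energy([2.0, 4.0], k=10) == 3.0


class ConstantBackend:
    name = "constant"
    deterministic = True

    def __init__(self, c):
        self.c = c

    def evaluate(self, model):
        return self.c


class TestEBind:
    def test_constant_backend_arithmetic(self, templates, ideal_1a, det_config):
        seq, phis, match = ideal_1a
        res = e_bind(seq, match, templates, ConstantBackend(4.0), det_config,
                     seed=0, compute_rsa=False)
        assert res.e_bind_mean == pytest.approx(-4.0)
        res0 = e_bind(seq, match, templates, ConstantBackend(0.0), det_config,
                      seed=0, compute_rsa=False)
        assert res0.e_bind_mean == pytest.approx(0.0)

    def test_seeded_result_identical_to_last_bit(self, templates, ideal_1a,
                                                 backend, minimal_config):
        seq, phis, match = ideal_1a
        a = e_bind(seq, match, templates, backend, minimal_config, seed=17)
        b = e_bind(seq, match, templates, backend, minimal_config, seed=17)
        assert a.e_bind_mean == b.e_bind_mean
        assert a.per_template == b.per_template
        assert a.e_bind_runs == b.e_bind_runs and a.rsa == b.rsa

    def test_energy_scaling_scales_e_bind(self, templates, ideal_1a, backend,
                                          det_config):
        seq, phis, match = ideal_1a
        base = e_bind(seq, match, templates, backend, det_config, seed=0,
                      compute_rsa=False)
        scaled = e_bind(seq, match, templates, ScaledBackend(backend, 3.0),
                        det_config, seed=0, compute_rsa=False)
        assert scaled.e_bind_mean == pytest.approx(3.0 * base.e_bind_mean)
        for tid in base.per_template:
            assert scaled.per_template[tid] == pytest.approx(
                3.0 * base.per_template[tid])

    @pytest.mark.parametrize("sub", ["A", "G"])
    def test_phi_substitution_never_lowers_e_bind(self, templates, ideal_1a,
                                                  backend, det_config, sub):
        seq, phis, match = ideal_1a
        base = e_bind(seq, match, templates, backend, det_config, seed=0,
                      compute_rsa=False).e_bind_mean
        for pos in phis:
            mutated = seq[:pos - 1] + sub + seq[pos:]
            m2 = match_from_registry(mutated, "1a", phis)
            res = e_bind(mutated, m2, templates, backend, det_config, seed=0,
                         compute_rsa=False)
            assert res.e_bind_mean > base

    def test_ideal_peptides_select_their_class(self, templates, backend,
                                               minimal_config):
        for cid in ("1a", "1b", "1c", "2", "4", "1a-R"):
            hits = 0
            for i in range(5):
                seq, phis, match = make_ideal_peptide(cid, 100 + i)
                res = e_bind(seq, match, templates, backend, minimal_config,
                             seed=i, compute_rsa=False)
                hits += res.best_class == cid
            assert hits >= 4, f"class {cid}: {hits}/5"

    def test_empty_template_library_rejected(self, ideal_1a, backend):
        seq, phis, match = ideal_1a
        with pytest.raises(ValueError):
            e_bind(seq, match, [], backend)


class TestInterfaceRSA:
    def test_isolated_sphere_fully_accessible(self):
        centers = np.array([[0.0, 0.0, 0.0]])
        fr = sasa.accessible_fractions(centers, np.array([2.0]))
        assert fr[0] == 1.0
        area = fr[0] * sasa.sphere_area(2.0)
        assert area == pytest.approx(4 * np.pi * 3.4 ** 2, rel=0.02)

    def test_enclosed_sphere_inaccessible(self):
        # centre sphere caged by a dense cubic shell of large spheres
        shell = [[x, y, z] for x in (-3, 0, 3) for y in (-3, 0, 3)
                 for z in (-3, 0, 3) if (x, y, z) != (0, 0, 0)]
        centers = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.array([1.5] + [2.2] * len(shell))
        fr = sasa.accessible_fractions(centers, radii, subset=np.array([0]))
        assert fr[0] < 0.05

    def test_ideal_complex_interface_nearly_buried(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        t = get_template(templates, "1a:6CIT")
        model = thread_peptide(seq, match, t)
        n_iface = 4 + int((cdist(t.groove.centroid, t.pockets).min(axis=1)
                           <= 6.0).sum())
        rsa = interface_rsa(model)
        assert rsa / 100.0 / n_iface < 0.05

    def test_translation_out_of_groove_increases_rsa(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        model = thread_peptide(seq, match, get_template(templates, "1a:6CIT"))
        shifted = model.copy()
        shifted.ca = shifted.ca + np.array([0.0, 0.0, 20.0])
        shifted.centroid = shifted.centroid + np.array([0.0, 0.0, 20.0])
        assert interface_rsa(shifted) > interface_rsa(model)

    def test_cavity_mutant_increases_rsa(self, templates, ideal_1a):
        seq, phis, match = ideal_1a
        t = get_template(templates, "1a:6CIT")
        base = interface_rsa(thread_peptide(seq, match, t))
        mutated = list(seq)
        for pos in phis[1:3]:
            mutated[pos - 1] = "A"
        mseq = "".join(mutated)
        m2 = match_from_registry(mseq, "1a", phis)
        assert interface_rsa(thread_peptide(mseq, m2, t)) > base

    def test_empty_interface_rejected(self, templates):
        t = get_template(templates, "1a:6CIT")
        model = strc.ComplexModel(
            template_id=t.template_id, template=t, aa="SS", slots=(0, 1),
            phi_mask=np.zeros(2, bool), ca=np.zeros((2, 3)),
            centroid=np.zeros((2, 3)), anchor_ca=np.zeros((2, 3)),
            has_groove=False,
        )
        with pytest.raises(ValueError, match="interface"):
            interface_rsa(model)


class TestRSACorrection:
    def _result(self, mean, rsa):
        return strc.BindingResult(
            per_template={}, best_template="1a:x", best_class="1a",
            e_bind=mean, e_bind_runs=[mean], e_bind_mean=mean, e_bind_sd=0.0,
            rsa=rsa, e_bind_rsa=0.0, weight_w=0.35,
        )

    def test_zero_weight_is_identity(self):
        res = rsa_correct(self._result(-10.0, 4.0), w=0.0)
        assert res.e_bind_rsa == -10.0

    def test_weighted_arithmetic(self):
        res = rsa_correct(self._result(-10.0, 4.0), w=0.35)
        assert res.e_bind_rsa == pytest.approx(-8.6)

    def test_strictly_increasing_in_rsa(self):
        lo = rsa_correct(self._result(-10.0, 2.0), w=0.35).e_bind_rsa
        hi = rsa_correct(self._result(-10.0, 5.0), w=0.35).e_bind_rsa
        assert hi > lo


class TestOptimizeRSAWeight:
    GRID = np.round(np.arange(0.0, 1.01, 0.05), 2)

    def test_constant_rsa_returns_smallest_weight(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=10)
        pairs = [(x, 3.0) for x in e]
        w = optimize_rsa_weight(pairs, 2.0 * e + 1.0, self.GRID)
        assert w == 0.0

    def test_planted_weight_recovered(self):
        rng = np.random.default_rng(1)
        e = rng.normal(scale=5.0, size=40)
        rsa = rng.normal(loc=20.0, scale=8.0, size=40)
        y = 0.7 * (e + 0.35 * rsa) + rng.normal(scale=0.3, size=40)
        w = optimize_rsa_weight(list(zip(e, rsa)), y, self.GRID)
        assert abs(w - 0.35) <= 0.05 + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            optimize_rsa_weight([(1.0, 1.0), (2.0, 2.0)], [1.0, 2.0], self.GRID)

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError):
            optimize_rsa_weight([(1.0, 1.0), (2.0, 2.0), (3.0, 1.0)],
                                [5.0, 5.0, 5.0], self.GRID)
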