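"""Architecture builders, connectome realization and circuit transforms."""

import numpy as np
import pytest

from cpgnet.network import (
    KnockoutSpec,
    LesionSpec,
    NetworkSpec,
    PopulationSpec,
    ProjectionSpec,
    apply_knockout,
    apply_lesion,
    build_model1,
    build_model2,
    build_unified,
    instantiate,
    mirror,
    scale_network,
)

# ---------------------------------------------------------------------------
# Frozen edge tables: multiset of (source role, target role, sign,
# commissural) per side, transcribed once from the circuit schematics.
# ---------------------------------------------------------------------------

_CORE_EDGES = [
    ("RG-F", "RG-F", "excitatory", False),
    ("RG-E", "RG-E", "excitatory", False),
    ("RG-F", "Inrg-F", "excitatory", False),
    ("Inrg-F", "RG-E", "inhibitory", False),
    ("RG-E", "Inrg-E", "excitatory", False),
    ("Inrg-E", "RG-F", "inhibitory", False),
    ("RG-F", "V0D", "excitatory", False),
    ("V0D", "RG-F", "inhibitory", True),
    ("RG-F", "V3", "excitatory", False),
    ("V3", "RG-F", "excitatory", True),
]

MODEL1_EDGES = sorted(
    (_CORE_EDGES + [
        ("RG-F", "V2a", "excitatory", False),
        ("V2a", "V0V", "excitatory", False),
        ("V0V", "InV0V", "excitatory", True),
        ("InV0V", "RG-F", "inhibitory", False),
    ]) * 2
)

MODEL2_EDGES = sorted(
    (_CORE_EDGES + [
        ("RG-E", "V2a", "excitatory", False),
        ("V2a", "V0V", "excitatory", False),
        ("V0V", "RG-F", "excitatory", True),
    ]) * 2
)

UNIFIED_EXTRA = [
    ("RG-F", "V2b", "excitatory", False),
    ("RG-E", "V2b", "excitatory", False),
    ("V2b", "RG-E", "inhibitory", False),
    ("V2b", "RG-F", "inhibitory", False),
    ("V0D", "V1", "inhibitory", True),
    ("V1", "RG-E", "inhibitory", False),
    ("V1", "InV1", "inhibitory", False),
    ("InV1", "RG-F", "inhibitory", False),
    ("RG-F", "RG-E", "excitatory", False),
    ("RG-E", "RG-F", "excitatory", False),
]

UNIFIED_MODEL1_EDGES = sorted(MODEL1_EDGES + UNIFIED_EXTRA * 2)


class TestBuilders:
    def test_model1_roster(self):
        spec = build_model1()
        sizes = {p.name: p.size for p in spec.populations}
        for side in ("l", "r"):
            assert sizes[f"{side}-RG-F"] == 200
            assert sizes[f"{side}-RG-E"] == 200
            for role in ("Inrg-F", "Inrg-E", "V0D", "V3", "V2a", "V0V", "InV0V"):
                assert sizes[f"{side}-{role}"] == 50

    def test_model1_edge_table_matches_frozen_transcription(self):
        assert build_model1().edge_table() == MODEL1_EDGES

    def test_model2_edge_table_matches_frozen_transcription(self):
        assert build_model2().edge_table() == MODEL2_EDGES

    def test_unified_edge_table_matches_frozen_transcription(self):
        assert build_unified("model1").edge_table() == UNIFIED_MODEL1_EDGES

    def test_model2_has_no_relay_population(self):
        assert not any(p.role == "InV0V" for p in build_model2().populations)

    def test_model2_v2a_driven_by_extensor_center_only(self):
        spec = build_model2()
        in_edges = [pr for pr in spec.projections if pr.target.endswith("V2a")]
        assert in_edges and all(pr.source.endswith("RG-E") for pr in in_edges)
        assert all(pr.source[0] == pr.target[0] for pr in in_edges)  # ipsilateral

    @pytest.mark.parametrize("builder", [build_model1, build_model2,
                                         lambda: build_unified("model1")])
    def test_mirror_symmetry(self, builder):
        spec = builder()
        assert mirror(spec).canonical() == spec.canonical()

    @pytest.mark.parametrize("builder", [build_model1, build_model2])
    def test_commissural_projections_originate_from_cins(self, builder):
        for pr in builder().projections:
            if pr.commissural:
                role = pr.source.split("-", 1)[1]
                assert role in ("V0D", "V0V", "V3")

    def test_unified_extends_core_roster(self):
        spec = build_unified("model1")
        names = {p.name for p in spec.populations}
        for side in ("l", "r"):
            for role in ("V2b", "V1", "InV1"):
                assert f"{side}-{role}" in names

    def test_unified_v1_drive_is_tagged_contralateral(self):
        spec = build_unified("model1")
        drives = {d.target: d for d in spec.tonic_drives}
        assert drives["l-V1"].source_side == "r"
        assert drives["r-V1"].source_side == "l"

    def test_unknown_core_label_rejected(self):
        with pytest.raises(ValueError):
            build_unified("model3")

    def test_sign_consistency_with_source_role(self):
        inhibitory = {"V0D", "V1", "V2b", "Inrg-F", "Inrg-E", "InV0V", "InV1"}
        for pr in build_unified("model1").projections:
            role = pr.source.split("-", 1)[1]
            expected = "inhibitory" if role in inhibitory else "excitatory"
            assert pr.sign == expected


class TestInstantiate:
    def test_full_connectivity_realizes_complete_bipartite(self, tiny_pair_spec):
        conn = instantiate(tiny_pair_spec, seed=0)
        assert conn.synapse_count("l-RG-F", "l-RG-E") == 9

    def test_binomial_synapse_count(self):
        pops = (
            PopulationSpec("l-RG-F", "l", "RG-F", 200, -70.0, 0.0, True, 1.0, True),
            PopulationSpec("r-RG-F", "r", "RG-F", 200, -70.0, 0.0, True, 1.0, True),
        )
        projs = (ProjectionSpec("l-RG-F", "r-RG-F", "excitatory", 0.1, 0.1,
                                commissural=True),)
        conn = instantiate(NetworkSpec(pops, projs), seed=3)
        n = conn.synapse_count("l-RG-F", "r-RG-F")
        mean, sd = 4000.0, np.sqrt(4000 * 0.9)
        assert abs(n - mean) < 4 * sd

    def test_same_seed_is_bit_identical(self):
        spec = scale_network(build_model1(), 0.25)
        a = instantiate(spec, seed=42)
        b = instantiate(spec, seed=42)
        assert np.array_equal(a.syn_tgt, b.syn_tgt)
        assert np.array_equal(a.syn_w, b.syn_w)
        assert np.array_equal(a.E_L0, b.E_L0)

    def test_no_autapses(self, single_pop_connectome):
        conn = single_pop_connectome
        for i in range(conn.n_neurons):
            tgts = conn.syn_tgt[conn.syn_ptr[i]:conn.syn_ptr[i + 1]]
            assert i not in tgts

    def test_scale_preserves_expected_total_input(self):
        """Connection probability absorbs the scale factor (folding any
        excess into the weight), so expected in-degree x weight is
        preserved up to integer rounding of population sizes."""
        spec = build_model1()
        scaled = scale_network(spec, 0.25)
        for pr, prs in zip(spec.projections, scaled.projections):
            assert prs.p_connect == pytest.approx(min(1.0, pr.p_connect / 0.25))
            src = spec.population(pr.source).size
            srcs = scaled.population(prs.source).size
            assert prs.p_connect * srcs * prs.weight == pytest.approx(
                pr.p_connect * src * pr.weight, rel=0.1
            )


class TestLesions:
    def test_remove_both_v0_types(self):
        spec = apply_lesion(
            build_model1(), LesionSpec(removed_roles=frozenset({"V0D", "V0V"}))
        )
        roles = {p.role for p in spec.populations}
        assert "V0D" not in roles and "V0V" not in roles
        # non-incident projections untouched
        assert any(pr.source == "l-RG-F" and pr.target == "l-Inrg-F"
                   for pr in spec.projections)

    def test_hemisection_removes_commissural_paths_and_v1_drive(self):
        spec = apply_lesion(build_unified("model1"), LesionSpec(hemisection_side="l"))
        assert all(p.side == "r" for p in spec.populations)
        assert not any(pr.commissural for pr in spec.projections)
        assert not any(d.target.endswith("V1") for d in spec.tonic_drives)

    def test_absent_role_is_warned_noop(self, caplog):
        spec = build_model2()
        out = apply_lesion(spec, LesionSpec(removed_roles=frozenset({"InV0V"})))
        assert out.canonical() == spec.canonical()
        assert any("absent" in r.message for r in caplog.records)

    def test_lesion_is_pure(self):
        spec = build_model1()
        before = spec.canonical()
        apply_lesion(spec, LesionSpec(removed_roles=frozenset({"V0D"})))
        assert spec.canonical() == before

    def test_removing_v1_v2b_leaves_only_inrg_inhibitory_fe_paths(self):
        spec = apply_lesion(
            build_unified("model1"), LesionSpec(removed_roles=frozenset({"V1", "V2b"}))
        )
        # enumerate inhibitory length-2 paths RG-F -> X -> RG-E per side
        for side in ("l", "r"):
            mids = {
                pr.target for pr in spec.projections
                if pr.source == f"{side}-RG-F" and pr.sign == "excitatory"
            }
            inhibitors = {
                pr.source for pr in spec.projections
                if pr.target == f"{side}-RG-E" and pr.sign == "inhibitory"
            }
            assert mids & inhibitors == {f"{side}-Inrg-F"}


class TestKnockouts:
    def test_zero_fraction_is_identity(self):
        spec = build_model1()
        assert apply_knockout(spec, KnockoutSpec("Netrin1", 0.0)).canonical() == spec.canonical()

    def test_netrin1_spares_v3(self):
        spec = apply_knockout(build_model1(), KnockoutSpec("Netrin1", 0.8))
        for pr in spec.projections:
            role = pr.source.split("-", 1)[1]
            if pr.commissural and role in ("V0D", "V0V"):
                assert pr.crossing_fraction == pytest.approx(0.2)
            elif pr.commissural and role == "V3":
                assert pr.crossing_fraction == 1.0

    def test_dcc_affects_all_three_cin_classes(self):
        spec = apply_knockout(build_model1(), KnockoutSpec("DCC", 0.8))
        for pr in spec.projections:
            if pr.commissural:
                assert pr.crossing_fraction == pytest.approx(0.2)

    def test_epha4_reroutes_v2a_axons_across_midline(self):
        spec = apply_knockout(build_model1(), KnockoutSpec("EphA4", 0.8))
        v2a_edges = [pr for pr in spec.projections
                     if pr.source.endswith("V2a") and pr.target.endswith("V0V")]
        assert v2a_edges and all(
            pr.crossing_fraction == pytest.approx(0.2) for pr in v2a_edges
        )
        # the V0 family crossing is untouched
        for pr in spec.projections:
            if pr.commissural:
                assert pr.crossing_fraction == 1.0

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            KnockoutSpec("Slit", 0.5)

    def test_lesion_knockout_composition_commutes_on_disjoint_targets(self):
        base = build_model1()
        ko = KnockoutSpec("EphA4", 0.8)            # touches V2a->V0V only
        les = LesionSpec(removed_roles=frozenset({"V0D"}))  # disjoint projections
        a = apply_lesion(apply_knockout(base, ko), les)
        b = apply_knockout(apply_lesion(base, les), ko)
        assert a.canonical() == b.canonical()

    def test_rerouted_axons_target_homologous_population(self):
        """With crossing_fraction 0, every realized synapse of a nominally
        commissural projection lands on the ipsilateral homolog."""
        pops = (
            PopulationSpec("l-V0D", "l", "V0D", 10, -64.0, 0.0, True, 0.0, False),
            PopulationSpec("l-RG-F", "l", "RG-F", 10, -70.0, 0.0, True, 1.0, True),
            PopulationSpec("r-RG-F", "r", "RG-F", 10, -70.0, 0.0, True, 1.0, True),
        )
        projs = (ProjectionSpec("l-V0D", "r-RG-F", "inhibitory", 1.0, 0.1,
                                commissural=True, crossing_fraction=0.0),)
        conn = instantiate(NetworkSpec(pops, projs), seed=1)
        assert conn.synapse_count("l-V0D", "r-RG-F") == 0
        assert conn.synapse_count("l-V0D", "l-RG-F") == 100
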