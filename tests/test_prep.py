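"""Irreversible splitting, FVA, blocked-reaction removal, candidate
selection and the maintenance/relaxation edits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcdesign import (
    ExclusionRules,
    InfeasibleError,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    RelaxationSpec,
    add_redox_ngam,
    apply_relaxations,
    flux_variability,
    make_fixture,
    optimize_flux,
    remove_blocked,
    select_candidates,
    set_ngam,
    split_reversible,
)
from gcdesign.core import INF


def _shuttle_model():
    """Tiny net with one reversible reaction: in -> a <-> b -> out."""
    return MetabolicModel(
        metabolites=[Metabolite("a"), Metabolite("b")],
        reactions=[
            Reaction("in_a", {"a": 1.0}, lb=0.0, ub=10.0, tags=frozenset({"exchange"})),
            Reaction("shuttle", {"a": -1.0, "b": 1.0}, lb=-5.0, ub=8.0),
            Reaction("out_b", {"b": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
        ],
        biomass_id="out_b",
    )


class TestSplitReversible:
    def test_reversible_reaction_splits_with_swapped_bounds(self):
        irr = split_reversible(_shuttle_model())
        fwd = irr.base.reaction("shuttle_fwd")
        rev = irr.base.reaction("shuttle_rev")
        assert (fwd.lb, fwd.ub) == (0.0, 8.0)
        assert (rev.lb, rev.ub) == (0.0, 5.0)
        assert rev.stoichiometry == {"a": 1.0, "b": -1.0}
        B = irr.mapping_matrix()
        col = B[:, irr.parent_ids.index("shuttle")].toarray().ravel()
        assert col.sum() == 2

    def test_irreversible_model_maps_to_identity(self, t1_model):
        irr = split_reversible(t1_model)
        assert irr.n_reactions == len(t1_model.reactions) == 7
        B = irr.mapping_matrix().toarray()
        assert np.array_equal(B, np.eye(7))

    def test_reaction_count_grows_by_number_of_reversibles(self):
        model = _shuttle_model()
        assert split_reversible(model).n_reactions == len(model.reactions) + 1

    def test_positive_lower_bound_kept_on_forward_copy(self, t1_model):
        irr = split_reversible(t1_model)
        assert irr.base.reaction("ATPM").lb == 1.0

    def test_mapping_matrix_row_and_column_structure(self):
        irr = split_reversible(_shuttle_model())
        B = irr.mapping_matrix().toarray()
        assert (B.sum(axis=1) == 1).all()  # every split copy has one parent
        assert set(B.sum(axis=0)) <= {1, 2}

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(st.integers(min_value=0, max_value=40))
    def test_split_preserves_net_flux_ranges(self, seed):
        """The split model's net parent fluxes span exactly the reversible
        model's FVA ranges (polytope preservation)."""
        model, _ = make_fixture("random", seed=seed)
        irr = split_reversible(model)
        for rid in model.reaction_ids:
            lo, hi = (
                optimize_flux(model, rid, "min").objective,
                optimize_flux(model, rid, "max").objective,
            )
            net = irr.net_flux_coefficients(rid)
            lo2 = optimize_flux(irr.base, net, "min").objective
            hi2 = optimize_flux(irr.base, net, "max").objective
            assert lo2 == pytest.approx(lo, abs=1e-7)
            assert hi2 == pytest.approx(hi, abs=1e-7)


class TestFluxVariability:
    def test_t1_ranges(self, t1_model):
        ranges = flux_variability(t1_model)
        # ATPM lower bound forces at least one unit of ATP turnover
        assert ranges.loc["ATPM", "min"] == pytest.approx(1.0, abs=1e-9)
        # all substrate may run through the byproduct route, ATPM absorbs the ATP
        assert ranges.loc["EX_P", "max"] == pytest.approx(10.0, abs=1e-9)
        assert ranges.loc["EX_P", "min"] == pytest.approx(0.0, abs=1e-9)

    def test_pinned_reaction_reports_its_value(self, t1_model):
        ranges = flux_variability(t1_model, fixed={"uptake": 3.0})
        assert ranges.loc["uptake", "min"] == pytest.approx(3.0)
        assert ranges.loc["uptake", "max"] == pytest.approx(3.0)

    def test_dead_end_metabolite_forces_zero(self):
        model = MetabolicModel(
            metabolites=[Metabolite("a"), Metabolite("dead")],
            reactions=[
                Reaction("in_a", {"a": 1.0}, lb=0.0, ub=10.0, tags=frozenset({"exchange"})),
                Reaction("out_a", {"a": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
                Reaction("to_dead", {"a": -1.0, "dead": 1.0}, lb=0.0, ub=INF),
            ],
            biomass_id="out_a",
        )
        ranges = flux_variability(model)
        assert ranges.loc["to_dead"].abs().max() < 1e-9

    def test_infeasible_fixing_raises(self, t1_model):
        with pytest.raises(InfeasibleError):
            flux_variability(t1_model, fixed={"uptake": 0.0})  # ATPM lb unmet


class TestRemoveBlocked:
    def test_removes_route_without_sink(self, t1_model):
        crippled = t1_model.copy()
        crippled.remove_reactions({"EX_P"})
        trimmed = remove_blocked(crippled)
        assert not trimmed.has_reaction("R_atp_by")  # P has no sink
        assert not trimmed.has_metabolite("P")

    def test_intact_model_unchanged_and_idempotent(self, t1_model):
        once = remove_blocked(t1_model)
        assert once.reaction_ids == t1_model.reaction_ids
        twice = remove_blocked(once)
        assert twice.reaction_ids == once.reaction_ids


class TestSelectCandidates:
    def test_t1_candidates(self, t1_model):
        # R_bm essential, exchanges and ATPM excluded by tag
        assert select_candidates(t1_model) == {"R_atp_clean", "R_atp_by"}

    def test_excluded_subsystem_filtered(self, t1_model):
        model = t1_model.copy()
        model.reaction("R_atp_by").subsystem = "tRNA charging"
        assert select_candidates(model) == {"R_atp_clean"}

    def test_candidates_never_lethal(self, t1_model):
        from gcdesign import max_growth

        for rid in select_candidates(t1_model):
            assert max_growth(t1_model, knockouts={rid}) > 1e-6


class TestMaintenanceEdits:
    def test_set_ngam_updates_lower_bound(self, t1_model):
        for value in (8.39, 4.2, 12.2):
            assert set_ngam(t1_model, value).reaction("ATPM").lb == value

    def test_negative_ngam_rejected(self, t1_model):
        with pytest.raises(ValueError):
            set_ngam(t1_model, -1.0)

    def test_zero_ngam_abolishes_zero_growth_coupling(self, t1):
        """Without a positive maintenance demand the zero flux vector is
        admissible, so nothing is guaranteed at zero growth."""
        from gcdesign import inner_min_rate

        model, gt = t1
        relaxed = set_ngam(model, 0.0)
        irr = split_reversible(relaxed)
        assert inner_min_rate(irr, gt.optimal_deletions, 0.0, "EX_P") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_ngam_created_when_absent(self):
        model = MetabolicModel(
            metabolites=[Metabolite("atp_c", compartment="c")],
            reactions=[
                Reaction("in_atp", {"atp_c": 1.0}, lb=0.0, ub=10.0,
                         tags=frozenset({"exchange"})),
            ],
            biomass_id="in_atp",
        )
        out = set_ngam(model, 2.5)
        assert out.reaction("ATPM").lb == 2.5
        assert "maintenance" in out.reaction("ATPM").tags


def _redox_model():
    mets = [
        Metabolite("nad_c", compartment="c"),
        Metabolite("nadh_c", compartment="c"),
        Metabolite("h_c", compartment="c"),
        Metabolite("h_e", compartment="e"),
        Metabolite("atp_c", compartment="c"),
    ]
    rxns = [
        Reaction("in_nadh", {"nadh_c": 1.0}, lb=0.0, ub=10.0, tags=frozenset({"exchange"})),
        Reaction("out_nad", {"nad_c": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
        Reaction("out_h", {"h_c": -1.0}, lb=0.0, ub=INF, tags=frozenset({"exchange"})),
        Reaction("ATPM", {"atp_c": -1.0}, lb=0.0, ub=INF, tags=frozenset({"maintenance"})),
        Reaction("in_atp", {"atp_c": 1.0}, lb=0.0, ub=10.0, tags=frozenset({"exchange"})),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, biomass_id="out_nad")


class TestRedoxAndRelaxations:
    def test_redox_ngam_consumes_named_cofactor(self):
        out = add_redox_ngam(_redox_model(), "NADH", 5.0, 20.0)
        rxn = out.reaction("NGAM_NADH")
        assert (rxn.lb, rxn.ub) == (5.0, 20.0)
        assert rxn.stoichiometry["nadh_c"] == -1.0
        assert rxn.stoichiometry["nad_c"] == 1.0
        assert rxn.stoichiometry["h_c"] == 1.0  # proton released

    def test_redox_ngam_missing_species_raises(self, t1_model):
        with pytest.raises(ModelError):
            add_redox_ngam(t1_model, "NADH", 5.0, 20.0)

    def test_redox_ngam_invalid_range_raises(self):
        with pytest.raises(ValueError):
            add_redox_ngam(_redox_model(), "NADH", 20.0, 5.0)

    def test_empty_relaxation_spec_rejected(self, t1_model):
        with pytest.raises(ValueError):
            apply_relaxations(t1_model, RelaxationSpec())

    def test_atpm_relaxation_unbounds_maintenance(self, t1_model):
        out = apply_relaxations(t1_model, RelaxationSpec(atpm_reversible_unbounded=True))
        rxn = out.reaction("ATPM")
        assert math.isinf(rxn.lb) and rxn.lb < 0
        assert math.isinf(rxn.ub)

    def test_all_flags_add_three_reactions(self):
        model = _redox_model()
        model.add_metabolite(Metabolite("nadp_c", compartment="c"))
        model.add_metabolite(Metabolite("nadph_c", compartment="c"))
        out = apply_relaxations(
            model,
            RelaxationSpec(
                atpm_reversible_unbounded=True,
                free_nadh=True,
                free_nadph=True,
                free_proton_translocation=True,
            ),
        )
        assert len(out.reactions) == len(model.reactions) + 3
        assert math.isinf(out.reaction("ATPM").ub)

    def test_proton_relaxation_requires_two_compartments(self, t1_model):
        with pytest.raises(ModelError):
            apply_relaxations(t1_model, RelaxationSpec(free_proton_translocation=True))
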