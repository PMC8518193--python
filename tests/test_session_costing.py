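"""Per-session sum-product costing and its category decomposition."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from microcoi import Activity, CostInput, Service, activity_cost, session_cost
from microcoi.cost_inputs import CATEGORIES
from microcoi.session_costing import load_services


def _inputs():
    return {
        "hcw_physician": CostInput("hcw_physician", "physician minute",
                                   "human_resources", "per_minute", 1.0, 0.0),
        "gauze": CostInput("gauze", "gauze", "disposable_materials", "per_item", 1.5, 0.0),
        "cryo_unit": CostInput("cryo_unit", "cryo unit", "equipment", "per_minute",
                               0.1, 0.0),
        "podo": CostInput("podo", "podophyllin", "drugs", "per_item", 1.06, 0.0),
    }


class TestActivityCost:
    def test_worker_and_disposable(self):
        a = Activity("apply", duration=10.0, performed_by="physician",
                     resource_use={"gauze": 2.0})
        out = activity_cost(a, _inputs())
        assert out["human_resources"] == pytest.approx(10.0)
        assert out["disposable_materials"] == pytest.approx(3.0)
        assert sum(out.values()) == pytest.approx(13.0)

    def test_zero_quantities_cost_nothing(self):
        a = Activity("idle", resource_use={"gauze": 0.0, "podo": 0.0})
        assert all(v == 0.0 for v in activity_cost(a, _inputs()).values())

    def test_equipment_minutes_and_drug(self):
        a = Activity("treat", resource_use={"cryo_unit": 5.0, "podo": 1.0})
        out = activity_cost(a, _inputs())
        assert out["equipment"] == pytest.approx(0.5)
        assert out["drugs"] == pytest.approx(1.06)

    def test_unresolved_input_named(self):
        a = Activity("apply", resource_use={"mystery": 1.0})
        with pytest.raises(KeyError, match="mystery"):
            activity_cost(a, _inputs())

    def test_worker_minutes_must_match_duration(self):
        with pytest.raises(ValueError, match="duration"):
            Activity("apply", duration=10.0, performed_by="physician",
                     resource_use={"hcw_physician": 5.0})


class TestSessionCost:
    def test_additive_over_activities(self):
        svc = Service(
            "podophyllin",
            (
                Activity("a", duration=10.0, performed_by="physician"),
                Activity("b", duration=5.0, performed_by="physician",
                         resource_use={"podo": 1.0}),
            ),
        )
        out = session_cost(svc, _inputs())
        assert out.total == pytest.approx(16.06)
        assert out.by_category["human_resources"] == pytest.approx(15.0)
        assert out.by_category["drugs"] == pytest.approx(1.06)

    def test_single_activity_identity(self):
        act = Activity("a", duration=7.0, performed_by="physician",
                       resource_use={"gauze": 1.0})
        svc = Service("diagnosis", (act,))
        assert session_cost(svc, _inputs()).by_category == pytest.approx(
            activity_cost(act, _inputs())
        )

    def test_published_podophyllin_category_profile(self):
        """A service with the published per-category point costs sums to 12.45 —
        intentionally distinct from the published 12.08 per-session figure,
        which is a simulation mean."""
        cats = {
            "human_resources": 9.21,
            "infrastructure": 0.09,
            "drugs": 1.06,
            "disposable_materials": 2.01,
            "utilities": 0.08,
        }
        inputs = {
            f"x_{c}": CostInput(f"x_{c}", c, c, "per_item", v, 0.0)
            for c, v in cats.items()
        }
        svc = Service(
            "podophyllin",
            (Activity("bundle", resource_use={k: 1.0 for k in inputs}),),
        )
        out = session_cost(svc, inputs)
        assert out.total == pytest.approx(12.45)
        assert out.total != pytest.approx(12.08, abs=0.05)

    def test_unknown_service_id_rejected(self):
        with pytest.raises(ValueError, match="unknown service"):
            Service("acupuncture", (Activity("a"),))

    def test_empty_activity_list_rejected(self):
        with pytest.raises(ValueError, match="no activities"):
            Service("diagnosis", ())


@st.composite
def random_service(draw):
    ids = ["gauze", "podo", "cryo_unit"]
    acts = []
    for i in range(draw(st.integers(1, 4))):
        use = {
            x: draw(st.floats(min_value=0, max_value=50))
            for x in draw(st.lists(st.sampled_from(ids), unique=True))
        }
        acts.append(Activity(f"a{i}", resource_use=use))
    return Service("diagnosis", tuple(acts))


class TestInvariants:
    @given(random_service())
    def test_categories_conserve_total(self, svc):
        out = session_cost(svc, _inputs())
        assert sum(out.by_category.values()) == pytest.approx(out.total, rel=1e-9)

    @given(random_service(), st.floats(min_value=1.5, max_value=10))
    def test_linear_in_unit_costs(self, svc, factor):
        base = _inputs()
        scaled = {
            k: CostInput(k, v.label, v.category, v.basis,
                         v.mean_unit_cost * factor, 0.0)
            for k, v in base.items()
        }
        assert session_cost(svc, scaled).total == pytest.approx(
            factor * session_cost(svc, base).total, rel=1e-9
        )

    @given(random_service())
    def test_removing_a_resource_never_increases_cost(self, svc):
        full = session_cost(svc, _inputs())
        stripped = Service(
            svc.service_id,
            tuple(
                Activity(a.activity_id,
                         resource_use={k: q for k, q in a.resource_use.items()
                                       if k != "gauze"})
                for a in svc.activities
            ),
        )
        out = session_cost(stripped, _inputs())
        for cat in CATEGORIES:
            assert out.by_category[cat] <= full.by_category[cat] + 1e-12


def test_services_yaml_roundtrip(tmp_path, zero_noise_bundle):
    from microcoi.synthetic import write_bundle

    write_bundle(zero_noise_bundle, tmp_path)
    services = load_services(tmp_path / "services.yaml")
    assert set(services) == set(zero_noise_bundle.services)
    unit_index = {ci.input_id: ci for ci in zero_noise_bundle.inputs}
    for sid, svc in services.items():
        assert session_cost(svc, unit_index).total == pytest.approx(
            session_cost(zero_noise_bundle.services[sid], unit_index).total
        )
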