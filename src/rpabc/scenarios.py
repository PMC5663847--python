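"""Declarative demographic scenarios with priors, conditions and nested sets.

A :class:`DemographicScenario` is a template: parameter declarations (uniform or
log-uniform priors, in years or diploid individuals), deme size expressions,
and split/resize event templates whose times and sizes reference parameters by
name (simple arithmetic expressions over parameter names are allowed, e.g.
``"N_PY * f_PY"``).  Drawing from the priors under the declared inequality
conditions and realizing the template always yields a valid
:class:`~rpabc.coalsim.RealizedDemography`.

The module ships the three nested scenario sets of the inference workflow:

* step 1 — 10 branching orders for three populations (trichotomy, the three
  rooted bifurcations, and six serial-colonization chains);
* step 2 — 6 nested size-change scenarios on the trichotomy, including the
  ancestral founder-bottleneck scenario;
* step 3 — constant-size versus recent-collapse (within the last five
  generations) extensions of the step-2 winner.

Times are declared in years and converted with ``generation_time_years`` (10 by
default); sizes are diploid individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import yaml

from .coalsim import (DemographyError, MutationModel, RealizedDemography,
                      ResizeEvent, SamplingDesign, ScenarioDraw, SplitEvent)

POPS = ("XCSS", "PY", "TL")


class PriorError(ValueError):
    pass


@dataclass
class ParamSpec:
    name: str
    dist: str  # "uniform" | "loguniform"
    low: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.dist not in {"uniform", "loguniform"}:
            raise PriorError(f"unknown prior family {self.dist!r}")
        if not (self.low < self.high):
            raise PriorError(f"{self.name}: empty prior [{self.low}, {self.high}]")
        if self.dist == "loguniform" and self.low <= 0:
            raise PriorError(f"{self.name}: log-uniform needs positive bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(math.exp(rng.uniform(math.log(self.low),
                                          math.log(self.high))))


def _eval(expr: Any, params: dict[str, float]) -> float:
    """Evaluate a size/time expression: a number, a parameter name, or simple
    arithmetic over parameter names (no builtins)."""
    if isinstance(expr, (int, float)):
        return float(expr)
    return float(eval(expr, {"__builtins__": {}}, dict(params)))  # noqa: S307


@dataclass
class DemographicScenario:
    """Event-template scenario: the unit of ABC model choice."""

    name: str
    params: list[ParamSpec]
    populations: dict[str, Any]  # deme name -> size expression
    events: list[dict] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    generation_time_years: float = 10.0

    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    def draw_params(self, rng: np.random.Generator,
                    fixed: dict[str, float] | None = None,
                    max_attempts: int = 100_000) -> dict[str, float]:
        """Rejection-sample the prior until every declared condition holds."""
        fixed = fixed or {}
        for _ in range(max_attempts):
            values = {p.name: fixed.get(p.name, p.draw(rng))
                      for p in self.params}
            if all(bool(_eval(c, values)) for c in self.conditions):
                return values
        raise PriorError(
            f"{self.name}: conditions unsatisfiable within {max_attempts} draws")

    def realize(self, params: dict[str, float]) -> RealizedDemography:
        """Instantiate the demography (times converted from years to generations)."""
        gen = self.generation_time_years
        pops = {name: _eval(expr, params)
                for name, expr in self.populations.items()}
        events: list[SplitEvent | ResizeEvent] = []
        for ev in self.events:
            t = _eval(ev["time"], params) / gen
            if ev["kind"] == "split":
                events.append(SplitEvent(t, list(ev["derived"]), ev["ancestral"]))
            elif ev["kind"] == "resize":
                events.append(ResizeEvent(t, ev["population"],
                                          _eval(ev["size"], params)))
            else:
                raise DemographyError(f"unknown event kind {ev['kind']!r}")
        dem = RealizedDemography(populations=pops, events=events,
                                 generation_time_years=gen)
        dem.validate()
        return dem

    def to_dict(self) -> dict:
        return {"name": self.name,
                "params": [asdict(p) for p in self.params],
                "populations": dict(self.populations),
                "events": [dict(e) for e in self.events],
                "conditions": list(self.conditions),
                "generation_time_years": self.generation_time_years}

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicScenario":
        return cls(name=d["name"],
                   params=[ParamSpec(**p) for p in d["params"]],
                   populations=d["populations"], events=d["events"],
                   conditions=d.get("conditions", []),
                   generation_time_years=d.get("generation_time_years", 10.0))


@dataclass
class MutationPriors:
    """Priors over the mutation model, shared by every scenario of a set."""

    mu_mic: ParamSpec = field(default_factory=lambda: ParamSpec(
        "mu_mic", "loguniform", 1e-4, 1e-3, "per locus per generation"))
    p_gsm: ParamSpec = field(default_factory=lambda: ParamSpec(
        "p_gsm", "uniform", 0.0, 0.3, ""))
    mu_mt: ParamSpec = field(default_factory=lambda: ParamSpec(
        "mu_mt", "loguniform", 1e-8, 1e-6, "per site per generation"))
    kappa: float = 10.0
    range_bound: int = 40

    def draw(self, rng: np.random.Generator,
             fixed: dict[str, float] | None = None) -> MutationModel:
        fixed = fixed or {}
        return MutationModel(
            mu_mic=fixed.get("mu_mic", self.mu_mic.draw(rng)),
            p_gsm=fixed.get("p_gsm", self.p_gsm.draw(rng)),
            range_bound=self.range_bound,
            mu_mt=fixed.get("mu_mt", self.mu_mt.draw(rng)),
            kappa=self.kappa)

    def param_specs(self) -> list[ParamSpec]:
        return [self.mu_mic, self.p_gsm, self.mu_mt]

    def to_dict(self) -> dict:
        return {"mu_mic": asdict(self.mu_mic), "p_gsm": asdict(self.p_gsm),
                "mu_mt": asdict(self.mu_mt), "kappa": self.kappa,
                "range_bound": self.range_bound}

    @classmethod
    def from_dict(cls, d: dict) -> "MutationPriors":
        return cls(mu_mic=ParamSpec(**d["mu_mic"]), p_gsm=ParamSpec(**d["p_gsm"]),
                   mu_mt=ParamSpec(**d["mu_mt"]), kappa=d.get("kappa", 10.0),
                   range_bound=d.get("range_bound", 40))


@dataclass
class ScenarioSet:
    """Ordered competing scenarios sharing one sampling design and mutation priors."""

    name: str
    scenarios: list[DemographicScenario]
    design: SamplingDesign
    mutation_priors: MutationPriors = field(default_factory=MutationPriors)

    def __post_init__(self) -> None:
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise PriorError("scenario names must be unique")

    def scenario_names(self) -> list[str]:
        return [s.name for s in self.scenarios]

    def get(self, name: str) -> DemographicScenario:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise KeyError(name)

    def sample_prior(self, scenario: str | DemographicScenario,
                     seed: int | np.random.Generator,
                     fixed: dict[str, float] | None = None) -> ScenarioDraw:
        """One reproducible prior draw: parameters + demography + mutation model."""
        if isinstance(scenario, str):
            scenario = self.get(scenario)
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        params = scenario.draw_params(rng, fixed)
        mutation = self.mutation_priors.draw(rng, fixed)
        params = dict(params)
        params.update(mu_mic=mutation.mu_mic, p_gsm=mutation.p_gsm,
                      mu_mt=mutation.mu_mt)
        return ScenarioDraw(params=params,
                            demography=scenario.realize(params),
                            mutation=mutation, scenario=scenario.name)

    def prior_bounds(self, scenario: str) -> dict[str, tuple[float, float]]:
        out = {p.name: (p.low, p.high) for p in self.get(scenario).params}
        for p in self.mutation_priors.param_specs():
            out[p.name] = (p.low, p.high)
        return out

    def to_yaml(self, path=None) -> str:
        doc = {"name": self.name,
               "design": {"n_diploid": dict(self.design.n_diploid),
                          "n_mt": dict(self.design.n_mt),
                          "n_loci": self.design.n_loci,
                          "mt_length": self.design.mt_length},
               "mutation_priors": self.mutation_priors.to_dict(),
               "scenarios": [s.to_dict() for s in self.scenarios]}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "ScenarioSet":
        import os
        if os.path.exists(source):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        design = SamplingDesign(**doc["design"])
        return cls(name=doc["name"],
                   scenarios=[DemographicScenario.from_dict(d)
                              for d in doc["scenarios"]],
                   design=design,
                   mutation_priors=MutationPriors.from_dict(
                       doc["mutation_priors"]))


# ---------------------------------------------------------------------------
# Shipped scenario sets
# ---------------------------------------------------------------------------

def study_design() -> SamplingDesign:
    """Sampling dimensions of the three distinct populations (ABC side)."""
    return SamplingDesign(n_diploid={"PY": 58, "TL": 17, "XCSS": 17},
                          n_mt={"PY": 56, "TL": 17, "XCSS": 16},
                          n_loci=11, mt_length=597)


def _size_params(pops: Sequence[str] = POPS,
                 bounds: tuple[float, float] = (10.0, 20_000.0)
                 ) -> list[ParamSpec]:
    return [ParamSpec(f"N_{p}", "uniform", *bounds, "individuals")
            for p in pops]


def build_step1_topologies(design: SamplingDesign | None = None,
                           mutation_priors: MutationPriors | None = None
                           ) -> ScenarioSet:
    """The 10 branching-order scenarios for three populations.

    SC1 is the trichotomy (simultaneous three-way split); SC2-SC4 the three
    rooted bifurcating orders; SC5-SC10 the six serial-colonization chains in
    which each daughter population was founded from another daughter rather
    than directly from the ancestor.  Sizes constant within branches.
    """
    design = design or study_design()
    t_old = ParamSpec("T1", "uniform", 100.0, 5000.0, "years")
    t_mid = ParamSpec("T2", "uniform", 100.0, 5000.0, "years")
    t_young = ParamSpec("T3", "uniform", 100.0, 5000.0, "years")
    n_anc = ParamSpec("N_anc", "uniform", 10.0, 20_000.0, "individuals")
    scenarios = []

    sizes = {p: f"N_{p}" for p in POPS}
    scenarios.append(DemographicScenario(
        name="SC1", params=_size_params() + [n_anc, t_old],
        populations={**sizes, "ANC": "N_anc"},
        events=[{"kind": "split", "time": "T1",
                 "derived": list(POPS), "ancestral": "ANC"}]))

    bifurcations = [(("PY", "TL"), "XCSS"), (("XCSS", "TL"), "PY"),
                    (("XCSS", "PY"), "TL")]
    for k, (pair, outer) in enumerate(bifurcations, start=2):
        scenarios.append(DemographicScenario(
            name=f"SC{k}",
            params=_size_params() + [n_anc, t_old, t_mid],
            populations={**sizes, "ANC1": "N_anc", "ANC": "N_anc"},
            events=[{"kind": "split", "time": "T2",
                     "derived": list(pair), "ancestral": "ANC1"},
                    {"kind": "split", "time": "T1",
                     "derived": ["ANC1", outer], "ancestral": "ANC"}],
            conditions=["T1 > T2"]))

    import itertools
    for k, order in enumerate(itertools.permutations(POPS), start=5):
        first, second, third = order
        scenarios.append(DemographicScenario(
            name=f"SC{k}",
            params=_size_params() + [n_anc, t_old, t_mid, t_young],
            populations={**sizes, "ANC": "N_anc"},
            events=[{"kind": "split", "time": "T3",
                     "derived": [third], "ancestral": second},
                    {"kind": "split", "time": "T2",
                     "derived": [second], "ancestral": first},
                    {"kind": "split", "time": "T1",
                     "derived": [first], "ancestral": "ANC"}],
            conditions=["T1 > T2", "T2 > T3"]))
    return ScenarioSet("step1_topologies", scenarios, design,
                       mutation_priors or MutationPriors())


def _trichotomy_base() -> tuple[dict, list[dict]]:
    sizes = {p: f"N_{p}" for p in POPS}
    split = [{"kind": "split", "time": "T_isol2",
              "derived": list(POPS), "ancestral": "ANC"}]
    return sizes, split


def build_step2_sizechange(design: SamplingDesign | None = None,
                           mutation_priors: MutationPriors | None = None
                           ) -> ScenarioSet:
    """Six nested size-change scenarios on the trichotomy.

    SC1 constant; SC2 decline in the daughter populations since a time after
    the split; SC3 ancestral founder bottleneck (large N_anc2 -> N_founder for
    a short duration DB -> expansion to N_exp2, split at T_isol2); SC4 simple
    ancestral size change (no bottleneck phase); SC5 expansion in the daughter
    populations; SC6 size change in both ancestral and daughter branches.
    """
    design = design or study_design()
    t_isol = ParamSpec("T_isol2", "uniform", 100.0, 5000.0, "years")
    t_exp = ParamSpec("T_exp2", "uniform", 1000.0, 50_000.0, "years")
    t_chg = ParamSpec("T_chg", "uniform", 10.0, 5000.0, "years")
    db = ParamSpec("DB", "uniform", 10.0, 500.0, "years")
    n_exp = ParamSpec("N_exp2", "uniform", 10.0, 20_000.0, "individuals")
    n_anc2 = ParamSpec("N_anc2", "uniform", 10.0, 20_000.0, "individuals")
    n_founder = ParamSpec("N_founder", "uniform", 2.0, 500.0, "individuals")
    n_split = ParamSpec("N_split", "uniform", 10.0, 2000.0, "individuals")
    sizes, split = _trichotomy_base()
    daughters_to = lambda size_expr: [  # noqa: E731
        {"kind": "resize", "time": "T_chg", "population": p, "size": size_expr}
        for p in POPS]
    anc_change = [{"kind": "resize", "time": "T_exp2",
                   "population": "ANC", "size": "N_anc2"}]
    founder = [{"kind": "resize", "time": "T_exp2",
                "population": "ANC", "size": "N_founder"},
               {"kind": "resize", "time": "T_exp2 + DB",
                "population": "ANC", "size": "N_anc2"}]
    scenarios = [
        DemographicScenario(
            name="SC1", params=_size_params() + [n_exp, t_isol],
            populations={**sizes, "ANC": "N_exp2"}, events=split),
        DemographicScenario(
            name="SC2", params=_size_params() + [n_exp, t_isol, t_chg],
            populations={**sizes, "ANC": "N_exp2"},
            events=split + daughters_to("N_exp2"),
            conditions=["T_isol2 > T_chg"] + [f"N_exp2 > N_{p}" for p in POPS]),
        DemographicScenario(
            name="SC3",
            params=_size_params() + [n_exp, n_anc2, n_founder, t_isol, t_exp, db],
            populations={**sizes, "ANC": "N_exp2"},
            events=split + founder,
            conditions=["T_exp2 > T_isol2"]),
        DemographicScenario(
            name="SC4", params=_size_params() + [n_exp, n_anc2, t_isol, t_exp],
            populations={**sizes, "ANC": "N_exp2"},
            events=split + anc_change,
            conditions=["T_exp2 > T_isol2"]),
        DemographicScenario(
            name="SC5", params=_size_params() + [n_exp, n_split, t_isol, t_chg],
            populations={**sizes, "ANC": "N_exp2"},
            events=split + daughters_to("N_split"),
            conditions=["T_isol2 > T_chg"] + [f"N_{p} > N_split" for p in POPS]),
        DemographicScenario(
            name="SC6",
            params=_size_params() + [n_exp, n_anc2, t_isol, t_exp, t_chg],
            populations={**sizes, "ANC": "N_exp2"},
            events=split + daughters_to("N_exp2") + anc_change,
            conditions=["T_exp2 > T_isol2", "T_isol2 > T_chg"]),
    ]
    return ScenarioSet("step2_sizechange", scenarios, design,
                       mutation_priors or MutationPriors())


def build_step3_collapse(design: SamplingDesign | None = None,
                         mutation_priors: MutationPriors | None = None,
                         max_collapse_years: float = 50.0) -> ScenarioSet:
    """Constant-size versus recent-collapse extensions of the founder scenario.

    Both scenarios carry the step-2 winner's ancestry (founder bottleneck and
    trichotomous split).  SC2 adds an independent collapse in every daughter
    population at a shared time within the last ``max_collapse_years`` years
    (five generations by default), with free remnant fractions (log-uniform).
    """
    design = design or study_design()
    t_isol = ParamSpec("T_isol2", "uniform", 100.0, 5000.0, "years")
    t_exp = ParamSpec("T_exp2", "uniform", 1000.0, 50_000.0, "years")
    db = ParamSpec("DB", "uniform", 10.0, 500.0, "years")
    n_exp = ParamSpec("N_exp2", "uniform", 10.0, 20_000.0, "individuals")
    n_anc2 = ParamSpec("N_anc2", "uniform", 10.0, 20_000.0, "individuals")
    n_founder = ParamSpec("N_founder", "uniform", 2.0, 500.0, "individuals")
    t_coll = ParamSpec("T_coll", "uniform", 1.0, max_collapse_years, "years")
    remnants = [ParamSpec(f"f_{p}", "loguniform", 0.001, 1.0, "fraction")
                for p in POPS]
    sizes, split = _trichotomy_base()
    founder = [{"kind": "resize", "time": "T_exp2",
                "population": "ANC", "size": "N_founder"},
               {"kind": "resize", "time": "T_exp2 + DB",
                "population": "ANC", "size": "N_anc2"}]
    common = [n_exp, n_anc2, n_founder, t_isol, t_exp, db]
    collapse_events = [{"kind": "resize", "time": "T_coll",
                        "population": p, "size": f"N_{p}"} for p in POPS]
    scenarios = [
        DemographicScenario(
            name="SC1", params=_size_params() + common,
            populations={**sizes, "ANC": "N_exp2"},
            events=split + founder,
            conditions=["T_exp2 > T_isol2"]),
        DemographicScenario(
            name="SC2", params=_size_params() + common + [t_coll] + remnants,
            populations={p: f"N_{p} * f_{p}" for p in POPS} | {"ANC": "N_exp2"},
            events=split + founder + collapse_events,
            conditions=["T_exp2 > T_isol2", "T_isol2 > T_coll"]),
    ]
    return ScenarioSet("step3_collapse", scenarios, design,
                       mutation_priors or MutationPriors())
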