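"""Deterministic generator of synthetic MIAPPE datasets.

Six scenario archetypes cover the standard's hard modelling cases:

``field_network``
    A multi-local, multi-year field phenotyping network: the whole network
    is one investigation, each location one study spanning the year range,
    with the biological-material and observed-variable lists shared across
    studies, per-genotype plot units under the hierarchy
    study > genotype > plot, and a study-level unit carrying weather-station
    variables.
``forest_geo``
    Natural-population forest trees identified purely by geographic
    coordinates; material source not identified (impossible to describe
    before the coordinates-based identification was introduced).
``glasshouse_factorial``
    A controlled-environment factorial: factors with declared value lists
    (drought: rainfed / irrigated; nitrogen at three levels) crossed over
    pot units.
``time_series``
    Repeated observations of one variable on a thermal-time axis (growing
    degree days) and a repeated event series (same type and description,
    new date per occurrence).
``sensor_only``
    An observation unit containing no plant (a field sensor) that is still
    a valid object of observation.
``crossing_population``
    A cross of two parents recorded as the material source; each progeny is
    a distinct biological material with its own unique identifier.

Generation is a pure function of (scenario, params, seed). Content realism
is cosmetic (names and coordinates come from fixed vocabularies and
plausible European agricultural bounds); what matters is structure, and
every generated dataset validates with zero errors.

The module also ships the mutation harness: :func:`mutate` introduces
exactly one defect violating a named rule of the validator's registry, which
is how the rule registry itself is exercised.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field
from pathlib import Path

from miappe.model import (
    BiologicalMaterial,
    Dataset,
    DataFile,
    EnvironmentParameter,
    Event,
    ExperimentalDesign,
    ExperimentalFactor,
    GeoPoint,
    GrowthFacility,
    Investigation,
    MaterialSource,
    MethodRef,
    ObservationUnit,
    ObservedVariable,
    OntologyRef,
    Person,
    Sample,
    ScaleRef,
    Study,
    StudyLocation,
    TraitRef,
    build_dataset,
)
from miappe.validate import rule_registry

SCENARIOS = (
    "field_network",
    "forest_geo",
    "glasshouse_factorial",
    "time_series",
    "sensor_only",
    "crossing_population",
)


class UnknownScenarioError(ValueError):
    pass


class UnknownRuleError(ValueError):
    pass


class RuleNotMutableError(ValueError):
    """The requested defect cannot be introduced into this dataset."""


@dataclass
class ScenarioSpec:
    scenario: str
    params: dict = field(default_factory=dict)
    seed: int = 0


_SITES = [
    ("Clermont-Ferrand", "France", 45.77, 3.08),
    ("Gatersleben", "Germany", 51.82, 11.28),
    ("Wageningen", "Netherlands", 51.97, 5.66),
    ("Poznan", "Poland", 52.41, 16.93),
    ("Oeiras", "Portugal", 38.69, -9.31),
    ("Norwich", "United Kingdom", 52.63, 1.30),
]

_WHEAT_GENOTYPES = ["Apache", "Soissons", "Renan", "Recital", "Arezzo",
                    "Caphorn", "Rubisko", "Bermude"]

_PEOPLE = [
    ("A. Moreau", "data manager", "a.moreau@example.org"),
    ("B. Kowalski", "principal investigator", "b.kowalski@example.org"),
    ("C. Ferreira", "technician", "c.ferreira@example.org"),
    ("D. Janssen", "curator", "d.janssen@example.org"),
]

_VARIABLES = [
    ("PH_M_cm", "Plant height", "Plant height", "CO_321:0001301",
     "Measuring tape", "ruler from ground level to canopy top", "cm"),
    ("GY_Comp_tha", "Grain yield", "Grain yield", "CO_321:0001218",
     "Combine harvest", "plot combine, normalized to 15% moisture", "t/ha"),
    ("FLO_Obs_day", "Flowering time", "Flowering time", "CO_321:0501101",
     "Visual observation", "50% of spikes emerged", "days after sowing"),
    ("CT_IR_C", "Canopy temperature", "Canopy temperature", "CO_321:0001424",
     "Infrared thermometry", "handheld IR gun at solar noon", "degrees C"),
]

_WEATHER_VARIABLES = [
    ("AT_Sens_C", "Air temperature", "Air temperature", None,
     "Weather station sensor", "hourly mean at 2 m", "degrees C"),
    ("RF_Sens_mm", "Rainfall", "Rainfall", None,
     "Weather station rain gauge", "daily cumulative", "mm"),
]


def _person(spec: tuple[str, str, str]) -> Person:
    name, role, email = spec
    return Person(name=name, role=role, email=email)


def _variable(spec: tuple, time_scale: str | None = None) -> ObservedVariable:
    vid, name, trait, acc, method, mdesc, scale = spec
    return ObservedVariable(
        id=vid, name=name,
        trait=TraitRef(name=trait, accession=acc),
        method=MethodRef(name=method, description=mdesc),
        scale=ScaleRef(name=scale),
        time_scale=time_scale,
    )


def _jitter(rng: random.Random, base: float, spread: float) -> float:
    return round(base + rng.uniform(-spread, spread), 6)


def _base_investigation(scenario: str, seed: int, title: str) -> Investigation:
    return Investigation(
        id=f"doi:10.5072/miappe.{scenario}.{seed}",
        title=title,
        description=f"Synthetic {scenario.replace('_', ' ')} dataset "
                    f"(seed {seed}).",
        submission_date="2019-03-01",
        public_release_date="2019-09-01",
        license="CC BY 4.0",
        miappe_version="1.1",
        publications=["doi:10.1000/synthetic-example"],
        persons=[_person(_PEOPLE[0]), _person(_PEOPLE[1])],
    )


def _field_network(rng: random.Random, params: dict, seed: int) -> Investigation:
    locations = int(params.get("locations", 3))
    years = int(params.get("years", 2))
    genotypes = int(params.get("genotypes", 4))
    plots = int(params.get("plots_per_genotype", 2))
    start_year = 2015

    inv = _base_investigation("field_network", seed,
                              "Synthetic wheat field phenotyping network")
    shared_bms = [
        BiologicalMaterial(
            id=f"INRAE:{name.upper()}",
            organism=OntologyRef(label="Triticum aestivum",
                                 accession="NCBITaxon:4565"),
            genus="Triticum", species="aestivum",
            material_source=MaterialSource(
                id=f"NLD037:{name.upper()}-LOT1",
                description="gene bank seed lot"),
        )
        for name in rng.sample(_WHEAT_GENOTYPES, genotypes)
    ]
    shared_vars = [_variable(v) for v in _VARIABLES[:3]]
    weather_vars = [_variable(v) for v in _WEATHER_VARIABLES]
    nitrogen = ExperimentalFactor(
        type="nitrogen input level",
        description="contrasted nitrogen fertilisation regimes",
        values=["high nitrogen input", "low nitrogen input",
                "no nitrogen inputs"],
    )

    for loc_i, (site, country, lat, lon) in enumerate(
            rng.sample(_SITES, locations)):
        sid = f"{inv.id}/study/{site.lower().replace(' ', '-')}"
        study = Study(
            id=sid,
            title=f"Wheat trial at {site}, {start_year}-{start_year + years}",
            description="One location of the network, run over "
                        f"{years + 1} seasons.",
            start_date=f"{start_year}-10-{10 + loc_i:02d}",
            end_date=f"{start_year + years}-07-{15 + loc_i:02d}",
            contact_institution="INRAE",
            location=StudyLocation(
                country=country, site_name=site,
                geo=GeoPoint(latitude=_jitter(rng, lat, 0.05),
                             longitude=_jitter(rng, lon, 0.05),
                             altitude=round(rng.uniform(20, 400), 1)),
            ),
            experimental_design=ExperimentalDesign(
                description="randomized complete block design, two blocks",
                type=OntologyRef(label="complete block design",
                                 accession="OBI:0500007"),
            ),
            growth_facility=GrowthFacility(
                description="open field",
                type=OntologyRef(label="field environment condition",
                                 accession="PECO:0007162"),
            ),
            cultural_practices="conventional tillage, fungicide as needed",
            observation_unit_level_hierarchy=["study", "genotype", "plot"],
            environments=[
                EnvironmentParameter(parameter="sowing density",
                                     value="300 seeds/m2"),
                EnvironmentParameter(parameter="rooting medium",
                                     value="field soil, loam"),
            ],
            factors=[copy.deepcopy(nitrogen)],
            biological_materials=copy.deepcopy(shared_bms),
            observed_variables=copy.deepcopy(shared_vars + weather_vars),
            persons=[_person(_PEOPLE[2 + loc_i % 2])],
        )
        station = ObservationUnit(
            id=f"{site}-station", level="study",
            spatial_distribution=[("station position", "field margin")],
        )
        study.observation_units.append(station)
        for g_i, bm in enumerate(shared_bms):
            g_unit = ObservationUnit(
                id=f"{site}-G{g_i + 1}", level="genotype",
                biological_material_id=bm.id,
            )
            study.observation_units.append(g_unit)
            for p_i in range(plots):
                study.observation_units.append(ObservationUnit(
                    id=f"{site}-G{g_i + 1}-P{p_i + 1}", level="plot",
                    biological_material_id=bm.id,
                    spatial_distribution=[
                        ("block", str(p_i + 1)),
                        ("row", str(rng.randint(1, 12))),
                    ],
                    factor_values={
                        "nitrogen input level":
                            nitrogen.values[(g_i + p_i) % 3],
                    },
                ))
        study.samples = [
            Sample(
                id=f"{site}-SAMP{k + 1}",
                observation_unit_id=f"{site}-G1-P{k % plots + 1}",
                collection_date=f"{start_year + 1}-06-{10 + k:02d}",
                description="flag leaf punch for protein assay",
                plant_anatomical_entity=OntologyRef(
                    label="leaf", accession="PO:0025034"),
            )
            for k in range(2)
        ]
        study.events = [
            Event(type=OntologyRef(label="sowing",
                                   accession="CO_715:0000007"),
                  description="autumn sowing",
                  date=study.start_date),
            *[
                Event(type=OntologyRef(label="fertilizing",
                                       accession="CO_715:0000011"),
                      description="nitrogen application",
                      date=f"{start_year + 1}-0{3 + k}-05")
                for k in range(2)
            ],
        ]
        study.data_files = [
            DataFile(link=f"data_{site.lower().replace(' ', '-')}_1.tsv",
                     description="plot-level agronomic observations",
                     version="1.0"),
            DataFile(link=f"data_{site.lower().replace(' ', '-')}_wx.tsv",
                     description="weather station time series",
                     version="1.0"),
        ]
        inv.studies.append(study)
    return inv


def _forest_geo(rng: random.Random, params: dict, seed: int) -> Investigation:
    trees = int(params.get("trees", 10))
    inv = _base_investigation("forest_geo", seed,
                              "Synthetic cork oak natural population survey")
    base_lat, base_lon = 38.78, -8.97
    study = Study(
        id=f"{inv.id}/study/montado",
        title="Cork oak stand survey",
        start_date="2016-02",
        end_date="2018-11",
        contact_institution="iBET",
        location=StudyLocation(
            country="Portugal", site_name="Montado stand A",
            geo=GeoPoint(latitude=base_lat, longitude=base_lon),
        ),
        experimental_design=ExperimentalDesign(
            description="observational survey of a natural population"),
        growth_facility=GrowthFacility(description="natural forest stand"),
        observation_unit_level_hierarchy=["study", "plant"],
        observed_variables=[
            _variable(("CBH_M_cm", "Circumference at breast height",
                       "Stem circumference", None, "Measuring tape",
                       "at 1.30 m above ground", "cm")),
            _variable(_VARIABLES[3]),
        ],
        data_files=[DataFile(link="data_montado_1.tsv",
                             description="per-tree measurements",
                             version="1.0")],
    )
    for t in range(trees):
        geo = GeoPoint(
            latitude=_jitter(rng, base_lat, 0.01),
            longitude=_jitter(rng, base_lon, 0.01),
            altitude=round(rng.uniform(120, 180), 1),
            coordinates_uncertainty=round(rng.uniform(2, 8), 1),
        )
        bm = BiologicalMaterial(
            id=f"QSUBER-TREE-{t + 1:03d}",
            organism=OntologyRef(label="Quercus suber",
                                 accession="NCBITaxon:58331"),
            genus="Quercus", species="suber",
            geo=geo,  # identification purely by coordinates
        )
        study.biological_materials.append(bm)
        study.observation_units.append(ObservationUnit(
            id=f"TREE-{t + 1:03d}", level="plant",
            biological_material_id=bm.id,
        ))
    inv.studies.append(study)
    return inv


def _glasshouse_factorial(rng: random.Random, params: dict,
                          seed: int) -> Investigation:
    genotypes = int(params.get("genotypes", 3))
    replicates = int(params.get("replicates", 2))
    inv = _base_investigation("glasshouse_factorial", seed,
                              "Synthetic barley glasshouse factorial")
    drought = ExperimentalFactor(
        type="drought",
        description="watering regime discriminating rainfed and irrigated "
                    "blocks",
        values=["rainfed", "irrigated"],
    )
    study = Study(
        id=f"{inv.id}/study/gh1",
        title="Automated glasshouse drought experiment",
        start_date="2017-03-01",
        end_date="2017-07-20",
        contact_institution="IPK",
        location=StudyLocation(country="Germany",
                               site_name="Gatersleben glasshouse 3"),
        experimental_design=ExperimentalDesign(
            description="full factorial, randomized pot positions"),
        growth_facility=GrowthFacility(
            description="automated conveyor glasshouse",
            type=OntologyRef(label="growth chamber study",
                             accession="PECO:0007061"),
        ),
        cultural_practices="daily automated weighing and watering",
        observation_unit_level_hierarchy=["study", "pot"],
        environments=[
            EnvironmentParameter(parameter="rooting medium",
                                 value="85% substrate, 15% sand"),
            EnvironmentParameter(parameter="photoperiod", value="16 h"),
        ],
        factors=[drought],
        observed_variables=[_variable(v) for v in _VARIABLES[:2]],
        data_files=[DataFile(link="data_gh1_1.tsv",
                             description="imaging-derived biomass estimates",
                             version="2.1")],
        persons=[_person(_PEOPLE[3])],
    )
    for g in range(genotypes):
        bm = BiologicalMaterial(
            id=f"DEU146:HOR{g + 1:04d}",
            organism=OntologyRef(label="Hordeum vulgare",
                                 accession="NCBITaxon:4513"),
            genus="Hordeum", species="vulgare",
            material_source=MaterialSource(id=f"DEU146:HOR{g + 1:04d}-SRC",
                                           description="gene bank accession"),
            preprocessing="seeds stratified at 4 degrees for 48 h",
        )
        study.biological_materials.append(bm)
        pot = 0
        for value in drought.values:
            for r in range(replicates):
                pot += 1
                study.observation_units.append(ObservationUnit(
                    id=f"GH1-G{g + 1}-POT{pot}", level="pot",
                    biological_material_id=bm.id,
                    spatial_distribution=[("lane", str(rng.randint(1, 6)))],
                    factor_values={"drought": value},
                ))
    study.samples = [
        Sample(id=f"GH1-SAMP{k + 1}",
               observation_unit_id=study.observation_units[k].id,
               collection_date=f"2017-06-{12 + k:02d}T10:30:00",
               description="youngest fully expanded leaf",
               plant_anatomical_entity=OntologyRef(label="leaf",
                                                   accession="PO:0025034"),
               plant_structure_development_stage=OntologyRef(
                   label="flowering stage", accession="PO:0007616"))
        for k in range(min(2, len(study.observation_units)))
    ]
    inv.studies.append(study)
    return inv


def _time_series(rng: random.Random, params: dict, seed: int) -> Investigation:
    plots = int(params.get("plots", 4))
    occurrences = int(params.get("event_occurrences", 3))
    inv = _base_investigation("time_series", seed,
                              "Synthetic maize time-series observations")
    study = Study(
        id=f"{inv.id}/study/ts1",
        title="Repeated canopy observations on a thermal-time axis",
        start_date="2018-04-20",
        end_date="2018-10-05",
        contact_institution="VIB",
        location=StudyLocation(
            country="Belgium", site_name="Ghent trial field",
            geo=GeoPoint(latitude=51.05, longitude=3.73),
        ),
        experimental_design=ExperimentalDesign(
            description="single block, repeated measurements"),
        growth_facility=GrowthFacility(description="open field"),
        observation_unit_level_hierarchy=["study", "plot"],
        observed_variables=[
            _variable(_VARIABLES[3], time_scale="growing degree days"),
        ],
        data_files=[DataFile(link="data_ts1_1.tsv",
                             description="canopy temperature time series, "
                                         "one timestamped row per "
                                         "observation",
                             version="1.0")],
    )
    bm = BiologicalMaterial(
        id="VIB:B104",
        organism=OntologyRef(label="Zea mays", accession="NCBITaxon:4577"),
        genus="Zea", species="mays",
        material_source=MaterialSource(id="USA970:B104-LOT3"),
    )
    study.biological_materials.append(bm)
    for p in range(plots):
        study.observation_units.append(ObservationUnit(
            id=f"TS1-P{p + 1}", level="plot",
            biological_material_id=bm.id,
            spatial_distribution=[("row", str(p + 1))],
        ))
    study.events = [
        Event(type=OntologyRef(label="irrigation",
                               accession="CO_715:0000015"),
              description="drip irrigation 20 mm",
              date=f"2018-0{6 + k}-10",
              affected_units=[f"TS1-P{p + 1}" for p in range(plots // 2)])
        for k in range(occurrences)
    ]
    inv.studies.append(study)
    return inv


def _sensor_only(rng: random.Random, params: dict, seed: int) -> Investigation:
    plots = int(params.get("plots", 2))
    inv = _base_investigation("sensor_only", seed,
                              "Synthetic field with a mid-field sensor unit")
    study = Study(
        id=f"{inv.id}/study/sensor1",
        title="Field microclimate monitoring",
        start_date="2018-05",
        end_date="2018-09",
        contact_institution="INRAE",
        location=StudyLocation(
            country="France", site_name="Montpellier field B",
            geo=GeoPoint(latitude=43.619261, longitude=3.87),
        ),
        experimental_design=ExperimentalDesign(
            description="uniform sowing with central sensor mast"),
        growth_facility=GrowthFacility(description="open field"),
        observation_unit_level_hierarchy=["study", "plot"],
        observed_variables=[_variable(v) for v in _WEATHER_VARIABLES],
        data_files=[DataFile(link="data_sensor1_1.tsv",
                             description="sensor mast microclimate series",
                             version="1.0")],
    )
    bm = BiologicalMaterial(
        id="INRAE:DURUM-SV1",
        organism=OntologyRef(label="Triticum turgidum subsp. durum",
                             accession="NCBITaxon:4567"),
        genus="Triticum", species="turgidum",
        infraspecific_name="subsp. durum",
    )
    study.biological_materials.append(bm)
    # the sensor: an observation unit containing no plant at all
    study.observation_units.append(ObservationUnit(
        id="SENSOR-MAST-1", level="plot",
        spatial_distribution=[("latitude", "+43.619261"),
                              ("longitude", "+3.870000")],
    ))
    for p in range(plots):
        study.observation_units.append(ObservationUnit(
            id=f"SV1-P{p + 1}", level="plot",
            biological_material_id=bm.id,
        ))
    inv.studies.append(study)
    return inv


def _crossing_population(rng: random.Random, params: dict,
                         seed: int) -> Investigation:
    progeny = int(params.get("progeny", 6))
    inv = _base_investigation("crossing_population", seed,
                              "Synthetic poplar crossing population")
    cross = MaterialSource(
        id="FRA040:CROSS-7156x7171",
        description="controlled cross of heterozygous parents "
                    "7156 (female) x 7171 (male)",
    )
    study = Study(
        id=f"{inv.id}/study/nursery",
        title="Progeny trial of a poplar cross",
        start_date="2014",
        end_date="2018",
        contact_institution="INRAE",
        location=StudyLocation(
            country="France", site_name="Orleans nursery",
            geo=GeoPoint(latitude=47.83, longitude=1.91),
        ),
        experimental_design=ExperimentalDesign(
            description="single-tree plots, randomized"),
        growth_facility=GrowthFacility(description="experimental nursery"),
        observation_unit_level_hierarchy=["study", "plant"],
        observed_variables=[
            _variable(("HT_M_cm", "Tree height", "Plant height",
                       "CO_357:1000021", "Telescopic pole",
                       "ground to apical bud", "cm")),
        ],
        data_files=[DataFile(link="data_nursery_1.tsv",
                             description="annual height measurements",
                             version="1.0")],
    )
    for g in range(progeny):
        bm = BiologicalMaterial(
            id=f"FRA040:POP-{g + 1:04d}",
            organism=OntologyRef(label="Populus deltoides x Populus nigra",
                                 accession="NCBITaxon:3691"),
            genus="Populus",
            material_source=copy.deepcopy(cross),
        )
        study.biological_materials.append(bm)
        study.observation_units.append(ObservationUnit(
            id=f"NUR-T{g + 1:03d}", level="plant",
            biological_material_id=bm.id,
            spatial_distribution=[("row", str(g // 3 + 1)),
                                  ("position", str(g % 3 + 1))],
        ))
    inv.studies.append(study)
    return inv


_BUILDERS = {
    "field_network": _field_network,
    "forest_geo": _forest_geo,
    "glasshouse_factorial": _glasshouse_factorial,
    "time_series": _time_series,
    "sensor_only": _sensor_only,
    "crossing_population": _crossing_population,
}


def generate(spec: ScenarioSpec | str, seed: int = 0,
             params: dict | None = None) -> Dataset:
    """Generate a synthetic dataset for a scenario.

    Accepts a :class:`ScenarioSpec` or a scenario name plus ``seed`` /
    ``params``. Same (scenario, params, seed) always yields an identical
    dataset.
    """
    if isinstance(spec, str):
        spec = ScenarioSpec(scenario=spec, params=params or {}, seed=seed)
    if spec.scenario not in _BUILDERS:
        raise UnknownScenarioError(
            f"unknown scenario {spec.scenario!r}; known: "
            f"{', '.join(SCENARIOS)}")
    rng = random.Random(spec.seed)
    investigation = _BUILDERS[spec.scenario](rng, spec.params, spec.seed)
    return build_dataset(investigation)


def write_data_files(dataset: Dataset, root_dir: str | Path,
                     seed: int = 0) -> list[Path]:
    """Materialize the observation data files a dataset links to.

    Writes one small TSV per data file (unit id, variable id, time, value)
    with uniform-noise values so that archive links resolve on disk. Only
    bare relative filenames are written; URLs are left alone.
    """
    rng = random.Random(seed)
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for study in dataset.investigation.studies:
        for df in study.data_files:
            if df.link is None or "://" in df.link or "/" in df.link:
                continue
            path = root / df.link
            rows = ["observation_unit_id\tvariable_id\ttime\tvalue"]
            for ou in study.observation_units:
                for var in study.observed_variables:
                    rows.append("\t".join([
                        ou.id or "-", var.id or "-",
                        study.start_date or "0",
                        f"{rng.uniform(0, 100):.2f}",
                    ]))
            path.write_text("\n".join(rows) + "\n", encoding="utf-8")
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# Mutation harness: one defect per registry rule.

def _first_study(inv: Investigation) -> Study:
    if not inv.studies:
        raise RuleNotMutableError("dataset has no studies")
    return inv.studies[0]


def _first(seq, what: str):
    for item in seq:
        return item
    raise RuleNotMutableError(f"dataset has no {what}")


def _mut_card_inv_study(inv, rng):
    inv.studies = []


def _mut_req_inv_id(inv, rng):
    inv.id = None


def _mut_fmt_version(inv, rng):
    inv.miappe_version = "1.0"


def _mut_card_stu_loc(inv, rng):
    _first_study(inv).location = None


def _mut_req_stu_id(inv, rng):
    _first_study(inv).id = None


def _mut_fmt_stu_dates(inv, rng):
    study = _first_study(inv)
    if study.start_date is None:
        raise RuleNotMutableError("study has no start date")
    study.end_date = "1900"


def _mut_card_stu_ou(inv, rng):
    # a fresh, otherwise-valid study with no observation units
    inv.studies.append(Study(
        id="SYNTH-EMPTY-STUDY", title="Empty follow-up study",
        location=StudyLocation(country="France"),
    ))


def _mut_req_per_name(inv, rng):
    persons = inv.persons or _first_study(inv).persons
    _first(persons, "persons").name = None


def _mut_req_per_role(inv, rng):
    persons = inv.persons or _first_study(inv).persons
    _first(persons, "persons").role = None


def _mut_df(fieldname):
    def mut(inv, rng):
        for study in inv.studies:
            if study.data_files:
                setattr(study.data_files[0], fieldname, None)
                return
        raise RuleNotMutableError("dataset has no data files")
    return mut


def _mut_req_bm_id(inv, rng):
    _first_study(inv).biological_materials.append(BiologicalMaterial(
        organism=OntologyRef(label="Zea mays", accession="NCBITaxon:4577"),
    ))


def _all_with_id(inv, attr: str, target_id: str):
    """Every occurrence of a (possibly study-shared) record with this id."""
    return [rec for study in inv.studies
            for rec in getattr(study, attr) if rec.id == target_id]


def _mut_req_bm_organism(inv, rng):
    for study in inv.studies:
        if study.biological_materials:
            target = study.biological_materials[0].id
            for bm in _all_with_id(inv, "biological_materials", target):
                bm.organism = None
            return
    raise RuleNotMutableError("dataset has no biological materials")


def _mut_req_env_fields(inv, rng):
    for study in inv.studies:
        if study.environments:
            study.environments[0].value = None
            return
    raise RuleNotMutableError("dataset has no environment parameters")


def _mut_uniq_env(inv, rng):
    for study in inv.studies:
        if study.environments:
            dup = study.environments[0]
            study.environments.append(EnvironmentParameter(
                parameter=dup.parameter, value="conflicting value"))
            return
    raise RuleNotMutableError("dataset has no environment parameters")


def _mut_req_fac_type(inv, rng):
    _first_study(inv).factors.append(ExperimentalFactor(
        type=None, values=["level A", "level B"]))


def _mut_req_fac_values(inv, rng):
    _first_study(inv).factors.append(ExperimentalFactor(
        type="placeholder factor", values=[]))


def _mut_req_ev_type(inv, rng):
    for study in inv.studies:
        if study.events:
            study.events[0].type = None
            return
    raise RuleNotMutableError("dataset has no events")


def _mut_req_ev_date(inv, rng):
    for study in inv.studies:
        if study.events:
            study.events[0].date = None
            return
    raise RuleNotMutableError("dataset has no events")


def _mut_ref_ev_ou(inv, rng):
    for study in inv.studies:
        if study.events:
            study.events[0].affected_units.append("NO-SUCH-UNIT")
            return
    raise RuleNotMutableError("dataset has no events")


def _mut_req_ou_level(inv, rng):
    for study in inv.studies:
        if study.observation_unit_level_hierarchy and study.observation_units:
            study.observation_units[0].level = "mezzanine"
            return
    raise RuleNotMutableError("no study with hierarchy and units")


def _mut_ref_ou_bm(inv, rng):
    for study in inv.studies:
        for ou in study.observation_units:
            if ou.biological_material_id is not None:
                ou.biological_material_id = "NO-SUCH-MATERIAL"
                return
    raise RuleNotMutableError("no unit references a biological material")


def _mut_card_sam_ou(inv, rng):
    for study in inv.studies:
        if study.samples:
            study.samples[0].observation_unit_id = None
            return
    raise RuleNotMutableError("dataset has no samples")


def _mut_ref_sam_ou(inv, rng):
    for study in inv.studies:
        if study.samples:
            study.samples[0].observation_unit_id = "NO-SUCH-UNIT"
            return
    raise RuleNotMutableError("dataset has no samples")


def _mut_req_sam_date(inv, rng):
    for study in inv.studies:
        if study.samples:
            study.samples[0].collection_date = None
            return
    raise RuleNotMutableError("dataset has no samples")


def _mut_warn_sam_range(inv, rng):
    for study in inv.studies:
        if study.samples and study.end_date:
            year = int(study.end_date[:4]) + 1
            study.samples[0].collection_date = f"{year}-01-15"
            return
    raise RuleNotMutableError("no sample within a dated study")


def _mut_req_var_components(inv, rng):
    for study in inv.studies:
        if study.observed_variables:
            target = study.observed_variables[0].id
            for var in _all_with_id(inv, "observed_variables", target):
                var.trait.name = None
            return
    raise RuleNotMutableError("dataset has no observed variables")


def _mut_fmt_date(inv, rng):
    inv.submission_date = "2017-06-31"  # impossible calendar date


def _mut_fmt_geo(inv, rng):
    for study in inv.studies:
        if study.location is not None and study.location.geo is not None:
            study.location.geo.latitude = 91.0
            return
        for bm in study.biological_materials:
            if bm.geo is not None:
                bm.geo.latitude = 91.0
                return
    raise RuleNotMutableError("dataset has no coordinates")


def _mut_fmt_curie(inv, rng):
    for study in inv.studies:
        for bm in study.biological_materials:
            if bm.organism is not None:
                for twin in _all_with_id(inv, "biological_materials", bm.id):
                    if twin.organism is not None:
                        twin.organism.accession = "not a term reference !!"
                return
    raise RuleNotMutableError("dataset has no organism references")


def _mut_fmt_factorvalue(inv, rng):
    for study in inv.studies:
        for ou in study.observation_units:
            if ou.factor_values:
                key = sorted(ou.factor_values)[0]
                ou.factor_values[key] = "undeclared modality"
                return
    raise RuleNotMutableError("no unit carries factor values")


_MUTATORS = {
    "CARD-INV-STUDY": _mut_card_inv_study,
    "REQ-INV-ID": _mut_req_inv_id,
    "FMT-MIAPPE-VERSION": _mut_fmt_version,
    "CARD-STU-LOC": _mut_card_stu_loc,
    "REQ-STU-ID": _mut_req_stu_id,
    "FMT-STU-DATES": _mut_fmt_stu_dates,
    "CARD-STU-OU": _mut_card_stu_ou,
    "REQ-PER-NAME": _mut_req_per_name,
    "REQ-PER-ROLE": _mut_req_per_role,
    "REQ-DF-LINK": _mut_df("link"),
    "REQ-DF-DESC": _mut_df("description"),
    "REQ-DF-VERSION": _mut_df("version"),
    "REQ-BM-ID": _mut_req_bm_id,
    "REQ-BM-ORGANISM": _mut_req_bm_organism,
    "REQ-ENV-FIELDS": _mut_req_env_fields,
    "UNIQ-ENV-PARAM": _mut_uniq_env,
    "REQ-FAC-TYPE": _mut_req_fac_type,
    "REQ-FAC-VALUES": _mut_req_fac_values,
    "REQ-EV-TYPE": _mut_req_ev_type,
    "REQ-EV-DATE": _mut_req_ev_date,
    "REF-EV-OU": _mut_ref_ev_ou,
    "REQ-OU-LEVEL": _mut_req_ou_level,
    "REF-OU-BM": _mut_ref_ou_bm,
    "CARD-SAM-OU": _mut_card_sam_ou,
    "REF-SAM-OU": _mut_ref_sam_ou,
    "REQ-SAM-DATE": _mut_req_sam_date,
    "WARN-SAM-DATE-RANGE": _mut_warn_sam_range,
    "REQ-VAR-COMPONENTS": _mut_req_var_components,
    "FMT-DATE": _mut_fmt_date,
    "FMT-GEO": _mut_fmt_geo,
    "FMT-CURIE": _mut_fmt_curie,
    "FMT-FACTORVALUE": _mut_fmt_factorvalue,
}

# every registry rule must have a mutator; checked at import time
_missing = {r.rule_id for r in rule_registry()} - set(_MUTATORS)
assert not _missing, f"rules without mutators: {_missing}"


def mutate(dataset: Dataset, rule_id: str, seed: int = 0) -> Dataset:
    """Return a copy of *dataset* with exactly one defect violating
    *rule_id*.

    Raises :class:`UnknownRuleError` for ids outside the rule registry and
    :class:`RuleNotMutableError` when the dataset lacks the structures the
    defect needs (e.g. no data files to corrupt).
    """
    if rule_id not in _MUTATORS:
        raise UnknownRuleError(f"unknown rule {rule_id!r}")
    investigation = copy.deepcopy(dataset.investigation)
    _MUTATORS[rule_id](investigation, random.Random(seed))
    return build_dataset(investigation)
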