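{
  "_comment": "In-vivo dermal study designs for the nine reference chemicals. Animal doses are mg/kg/day; human application areas (cm^2) are the BSA-scaled areas that close the published dose-conversion chains. fu_plasma, solubility, density and vehicle loads in the chemical fixture are assumed values (not reported in the source studies).",
  "studies": [
    {
      "chemical": "BR",
      "species": "rat",
      "animal_doses_mg_kg_day": [50, 200, 400],
      "noael": [false, false, true],
      "human_areas_cm2": [1344.0, 1344.0, 1344.0],
      "exposure_days": 20,
      "removal_after_h": null,
      "occlusion": "unoccluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "CAP",
      "species": "rat",
      "animal_doses_mg_kg_day": [64, 96, 128],
      "noael": [true, true, false],
      "human_areas_cm2": [1600.0, 2400.0, 3200.0],
      "exposure_days": 11,
      "removal_after_h": 3.0,
      "occlusion": "occluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "DGMME",
      "species": "rat",
      "animal_doses_mg_kg_day": [50, 250, 750],
      "noael": [true, false, false],
      "human_areas_cm2": [1066.6, 1066.6, 1066.6],
      "exposure_days": 13,
      "removal_after_h": null,
      "occlusion": "occluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "DGMBE",
      "species": "rat",
      "animal_doses_mg_kg_day": [100, 300, 1000],
      "noael": [false, false, true],
      "human_areas_cm2": [1066.6, 1066.6, 1066.6],
      "exposure_days": 13,
      "removal_after_h": 4.0,
      "occlusion": "unoccluded",
      "vehicle": {"type": "water", "mL_per_kg": 3.0}
    },
    {
      "chemical": "DMF",
      "species": "rat",
      "animal_doses_mg_kg_day": [100, 200, 400],
      "noael": [false, true, false],
      "human_areas_cm2": [48.0, 149.3, 352.0],
      "exposure_days": 13,
      "removal_after_h": 6.0,
      "occlusion": "semi-occluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "2-EH",
      "species": "rat",
      "animal_doses_mg_kg_day": [252, 840, 2520],
      "noael": [false, true, true],
      "human_areas_cm2": [620.9, 620.9, 620.9],
      "exposure_days": 10,
      "removal_after_h": 6.0,
      "occlusion": "occluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "MPA",
      "species": "rat",
      "animal_doses_mg_kg_day": [1000, 2000],
      "noael": [false, true],
      "human_areas_cm2": [1056.0, 1056.0],
      "exposure_days": 13,
      "removal_after_h": 6.0,
      "occlusion": "semi-occluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "2-ME",
      "species": "rat",
      "animal_doses_mg_kg_day": [840],
      "noael": [true],
      "human_areas_cm2": [620.9],
      "exposure_days": 10,
      "removal_after_h": 6.0,
      "occlusion": "occluded",
      "vehicle": {"type": "none"}
    },
    {
      "chemical": "TGA",
      "species": "rat",
      "animal_doses_mg_kg_day": [10, 25, 65],
      "noael": [false, false, true],
      "human_areas_cm2": [309.7, 309.7, 309.7],
      "exposure_days": 24,
      "removal_after_h": 6.0,
      "occlusion": "unoccluded",
      "vehicle": {"type": "water", "mL_per_kg": 2.0}
    }
  ]
}
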