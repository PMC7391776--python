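# Reference metabolic universe: 9 metabolites, 43 conversion reactions and
# 16 transport reactions (one importer and one exporter per non-energy
# metabolite).  Rates are per-time-step fractions; toxicity is the internal
# concentration above which a metabolite contributes to the death hazard;
# influx is the external supply per grid site per step (only the resource R
# is supplied).  Mass is carried for completeness but unused by the dynamics.
#
# Canonical reaction ordering: conversions below in listed order (indices
# 0..42), then importers in metabolite listing order (43..50), then
# exporters in the same order (51..58).
name: reference
metabolites:
  - {id: R,  mclass: resource,       diffusion: 0.011, degradation: 0.0003, toxicity: 0.0779, mass: 1.0, influx: 0.002}
  - {id: B1, mclass: building_block, diffusion: 0.011, degradation: 0.0100, toxicity: 0.0588, mass: 1.0, influx: 0.0}
  - {id: B2, mclass: building_block, diffusion: 0.012, degradation: 0.0100, toxicity: 0.1038, mass: 1.0, influx: 0.0}
  - {id: E,  mclass: energy,         diffusion: 0.050, degradation: 0.1000, toxicity: 0.0651, mass: 1.0, influx: 0.0}
  - {id: M1, mclass: intermediate,   diffusion: 0.014, degradation: 0.0006, toxicity: 0.1056, mass: 1.0, influx: 0.0}
  - {id: M2, mclass: intermediate,   diffusion: 0.019, degradation: 0.0003, toxicity: 0.0804, mass: 1.0, influx: 0.0}
  - {id: M3, mclass: intermediate,   diffusion: 0.013, degradation: 0.0006, toxicity: 0.0797, mass: 1.0, influx: 0.0}
  - {id: M4, mclass: intermediate,   diffusion: 0.014, degradation: 0.0014, toxicity: 0.1586, mass: 1.0, influx: 0.0}
  - {id: M5, mclass: intermediate,   diffusion: 0.016, degradation: 0.0008, toxicity: 0.0475, mass: 1.0, influx: 0.0}
conversions:
  - R -> B2 + E
  - B1 -> M4 + 2 E
  - M1 -> M2 + 2 E
  - M2 + M5 -> B1
  - M3 + M5 -> R
  - R -> B1 + E
  - B1 -> M5 + 3 E
  - M2 + M3 -> B1
  - M2 + M5 -> M1
  - M3 -> M5 + 2 E
  - R -> M1 + 3 E
  - B2 -> M1 + 2 E
  - M2 + M3 -> B2
  - 2 M1 -> R
  - M3 -> M4 + E
  - R -> M2 + 5 E
  - B2 -> M2 + 4 E
  - M2 + M5 -> M4
  - 2 M2 -> M1
  - M4 -> M2 + 2 E
  - R -> M4 + 3 E
  - B2 -> M3 + E
  - M2 + M4 -> M3
  - 2 M2 -> B1
  - M4 + M5 -> B2
  - R -> M5 + 4 E
  - B2 -> M4 + 2 E
  - M2 + M5 -> M3
  - 2 M2 -> B2
  - M4 + M5 -> R
  - R -> M3 + 2 E
  - B2 -> M5 + 3 E
  - M2 + M4 -> B2
  - 2 M2 -> M4
  - M4 + M5 -> B1
  - B1 -> M1 + 2 E
  - M1 + M4 -> R
  - M2 + M5 -> B2
  - 2 M2 -> M5
  - M5 -> M2 + E
  - B1 -> M2 + 4 E
  - M1 + M2 -> M3
  - M2 + M5 -> R
transports:
  importers: [R, B1, B2, M1, M2, M3, M4, M5]
  exporters: [R, B1, B2, M1, M2, M3, M4, M5]
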