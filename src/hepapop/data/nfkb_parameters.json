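{
  "description": "Parameters of the attached NF-kB/IkBa/A20 transcription module. Values transcribed from the published two-compartment NF-kB regulatory module this model adopts (original units: micromolar and seconds). Transcription was validated behaviourally: damped oscillations of free nuclear NF-kB under sustained TR=1, early activation within 30 min, exact conservation of total NF-kB, and a resting state dominated by the cytoplasmic IkBa:NF-kB complex. Three deliberate departures from the source, following the adopting model: (i) the cytoplasm:nucleus volume ratio kv is 3 (hepatocytes) instead of 5 (fibroblasts); (ii) all rate values are multiplied by 3600 at load time so the working unit is hours; (iii) the generic target-gene transcript is repurposed as P_mRNA with refitted synthesis (c1p) and degradation (c3p) constants; its inducible synthesis reads the nuclear NF-kB excess over the resting level and is gated by (1-ActD).",
  "volume_ratio": {"kv": 3.0},
  "resting_pools_uM": {"knn": 0.2, "nfkb_total": 0.06},
  "rates_per_second": {
    "kprod": 2.5e-5,
    "kdeg": 1.25e-4,
    "k1": 2.5e-3,
    "k2": 0.1,
    "k3": 1.5e-3,
    "a1": 0.5,
    "a2": 0.2,
    "a3": 1.0,
    "t1": 0.1,
    "t2": 0.1,
    "c1": 5.0e-7,
    "c2": 0.0,
    "c3": 4.0e-4,
    "c4": 0.5,
    "c5": 3.0e-4,
    "c1a": 5.0e-7,
    "c2a": 0.0,
    "c3a": 4.0e-4,
    "c4a": 0.5,
    "c5a": 1.0e-4,
    "c6a": 2.0e-5,
    "i1": 2.5e-3,
    "i1a": 1.0e-3,
    "e1a": 5.0e-4,
    "e2a": 1.0e-2
  },
  "p_gene_rates_per_hour": {
    "c1p": 30.0,
    "c2p": 0.0,
    "c3p": 0.5
  },
  "roles": {
    "kv": "cytoplasm:nucleus volume ratio",
    "knn": "resting neutral-IKK pool implied by kprod/kdeg",
    "kprod": "IKKn synthesis",
    "kdeg": "degradation of all IKK forms",
    "k1": "IKK activation upon TR",
    "k2": "A20-mediated IKK inactivation (requires TR)",
    "k3": "spontaneous IKK inactivation",
    "a1": "IkBa + NF-kB association (both compartments)",
    "a2": "IKKa + IkBa association",
    "a3": "IKKa + IkBa:NF-kB association",
    "t1": "catalytic IkBa degradation in IKKa:IkBa",
    "t2": "catalytic IkBa degradation in IKKa:IkBa:NF-kB (releases NF-kB)",
    "c1": "NF-kB-inducible A20 transcription",
    "c2": "constitutive A20 transcription",
    "c3": "A20 transcript degradation",
    "c4": "A20 translation",
    "c5": "A20 protein degradation",
    "c1a": "NF-kB-inducible IkBa transcription",
    "c2a": "constitutive IkBa transcription",
    "c3a": "IkBa transcript degradation",
    "c4a": "IkBa translation",
    "c5a": "free IkBa degradation",
    "c6a": "spontaneous IkBa degradation within IkBa:NF-kB",
    "i1": "NF-kB nuclear import",
    "i1a": "IkBa nuclear import",
    "e1a": "IkBa nuclear export",
    "e2a": "IkBan:NF-kBn nuclear export",
    "c1p": "NF-kB-inducible P_mRNA synthesis (refit)",
    "c2p": "constitutive P_mRNA synthesis (zero: only induced P is modelled)",
    "c3p": "P_mRNA degradation (refit)"
  }
}
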