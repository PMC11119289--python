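# pulfinder default configuration.
# Plain key = value; list values are ';'-separated; '#' starts a comment line.
# Every key understood by the pipeline appears here with its shipped default.

# --- gene role signatures -------------------------------------------------
# SusC-like: TonB-dependent receptor requires BOTH the plug and beta-barrel
# domains (a distinct linear domain sequence).
role.susc.require = PF00593;PF07715
# SusD-like: any one of the SusD/SusD-like domain family.
role.susd.any = PF07980;PF12741;PF12771;PF14322
# Sulfatase genes (accessory evidence for sulfated glycans such as fucoidan).
role.sulfatase.any = PF00884;SULFATASE
# Hybrid two-component system: sensor kinase + response regulator + AraC-type
# output domain fused on one gene.
role.htcs.require = PF00512;PF00072;PF12833
# Extracytoplasmic-function sigma factor: sigma70 region 2 + region 4.
role.ecf_sigma.require = PF04542;PF04545
# Anti-sigma factor (FecR-like).
role.anti_sigma.any = PF04773

# --- locus extension (gap rule) ------------------------------------------
gap.max_gap_genes = 2
gap.max_gap_bp = 5000
gap.pair_max_gap_genes = 0
# 'transcription' (upstream/downstream along the coding strand) or
# 'plus_coordinate' (upstream = lower plus-strand coordinate regardless of strand)
gap.pair_orientation = transcription

# --- substrate signatures (CAZyme families; SULFATASE matches sulfatase genes)
substrate.alginate.core = PL6;PL7;PL8
substrate.alginate.accessory =
substrate.fucoidan.core = GH29;GH95;GH141
substrate.fucoidan.accessory = SULFATASE
substrate.laminarin.core = GH3;GH16;GH51
substrate.laminarin.accessory =
substrate.porphyran.core = GH16;GH86
substrate.porphyran.accessory = GH2

# --- growth phase detection (OD600 units) --------------------------------
growth.baseline_delta = 0.05
growth.plateau_eps = 0.02

# --- SEC molecular-weight calibration ------------------------------------
# allowed extrapolation beyond the fitted retention-time domain, as a
# fraction of the domain width
sec.extrapolation_margin = 0.1
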