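# Reference D10 (dose at 10% clonogenic survival) and reported RBE for
# CHO wild-type and repair-deficient xrs5 cells under various radiation
# qualities, as compiled from published clonogenic-survival experiments.
# LET in keV/um ("" where not applicable).  rbe_*_reported are the
# published values; ratio-derived RBE (gamma D10 / test D10) can be
# recomputed with augerdose.rbe_pipeline.build_rbe_table.
radiation,let_kev_um,d10_cho_gy,rbe_cho_reported,d10_xrs5_gy,rbe_xrs5_reported
gamma,0.3,6.37,1.0,1.18,1.0
proton,1.1,5.31,1.20,1.16,1.02
carbon,13,3.79,1.68,0.91,1.30
carbon,70,2.49,2.56,0.94,1.26
iron,200,1.89,3.37,1.00,1.18
cu64,,2.23,2.53,0.92,1.12
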