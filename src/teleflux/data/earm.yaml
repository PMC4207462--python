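# Extrinsic Apoptosis Reaction Model (EARM v1.0) -- mass-action transcription
# of the published TRAIL-to-death kinetic model (Albeck et al. 2008, as used
# with synthesis/degradation by Spencer et al. 2009).  Rate constants are in
# per-second units (bimolecular: per molecule per second); membrane-localized
# bimolecular rates are pre-divided by the mitochondrial volume fraction
# v = 0.07.  Species levels are molecules per cell.
#
# The 17 "native" proteins listed under `natives` are the species that carry
# stochastic turnover models in the hybrid simulator; their `initial` values
# are the mean protein levels of the base model and are kept as stationary
# means when turnover is attached.
time_unit: s
species:
  - L
  - R
  - L_R
  - DISC
  - flip
  - flip_DISC
  - pC8
  - DISC_pC8
  - C8
  - BAR
  - BAR_C8
  - pC3
  - C8_pC3
  - C3
  - pC6
  - C3_pC6
  - C6
  - C6_pC8
  - XIAP
  - XIAP_C3
  - C3_U
  - PARP
  - C3_PARP
  - cPARP
  - Bid
  - C8_Bid
  - tBid
  - Mcl1
  - tBid_Mcl1
  - Bax
  - tBid_Bax
  - aBax
  - MBax
  - Bcl2
  - MBax_Bcl2
  - Bax2
  - Bax2_Bcl2
  - Bax4
  - Bax4_Bcl2
  - M
  - Bax4_M
  - AM
  - mCytoC
  - AM_mCytoC
  - aCytoC
  - cCytoC
  - Apaf
  - cCytoC_Apaf
  - aApaf
  - pC9
  - Apop
  - Apop_pC3
  - Apop_XIAP
  - mSmac
  - AM_mSmac
  - aSmac
  - cSmac
  - cSmac_XIAP
reactions:
  # receptor / DISC
  - "L + R -> L_R @ 4.0e-7"
  - "L_R -> L + R @ 1.0e-3"
  - "L_R -> DISC @ 1.0e-5"
  - "flip + DISC -> flip_DISC @ 1.0e-6"
  - "flip_DISC -> flip + DISC @ 1.0e-3"
  - "pC8 + DISC -> DISC_pC8 @ 1.0e-6"
  - "DISC_pC8 -> pC8 + DISC @ 1.0e-3"
  - "DISC_pC8 -> C8 + DISC @ 1.0"
  - "C8 + BAR -> BAR_C8 @ 1.0e-6"
  - "BAR_C8 -> C8 + BAR @ 1.0e-3"
  # executioner cascade
  - "pC3 + C8 -> C8_pC3 @ 1.0e-7"
  - "C8_pC3 -> pC3 + C8 @ 1.0e-3"
  - "C8_pC3 -> C3 + C8 @ 1.0"
  - "pC6 + C3 -> C3_pC6 @ 1.0e-7"
  - "C3_pC6 -> pC6 + C3 @ 1.0e-3"
  - "C3_pC6 -> C6 + C3 @ 1.0"
  - "pC8 + C6 -> C6_pC8 @ 3.0e-8"
  - "C6_pC8 -> pC8 + C6 @ 1.0e-3"
  - "C6_pC8 -> C8 + C6 @ 1.0"
  - "XIAP + C3 -> XIAP_C3 @ 2.0e-6"
  - "XIAP_C3 -> XIAP + C3 @ 1.0e-3"
  - "XIAP_C3 -> XIAP + C3_U @ 1.0e-1"
  - "PARP + C3 -> C3_PARP @ 1.0e-6"
  - "C3_PARP -> PARP + C3 @ 1.0e-2"
  - "C3_PARP -> cPARP + C3 @ 1.0"
  # mitochondrial pathway
  - "Bid + C8 -> C8_Bid @ 1.0e-7"
  - "C8_Bid -> Bid + C8 @ 1.0e-3"
  - "C8_Bid -> tBid + C8 @ 1.0"
  - "tBid + Mcl1 -> tBid_Mcl1 @ 1.0e-6"
  - "tBid_Mcl1 -> tBid + Mcl1 @ 1.0e-3"
  - "Bax + tBid -> tBid_Bax @ 1.0e-7"
  - "tBid_Bax -> Bax + tBid @ 1.0e-3"
  - "tBid_Bax -> aBax + tBid @ 1.0"
  - "aBax -> MBax @ 1.0e-2"
  - "MBax -> aBax @ 1.0e-2"
  - "MBax + Bcl2 -> MBax_Bcl2 @ 1.428571e-5"
  - "MBax_Bcl2 -> MBax + Bcl2 @ 1.0e-3"
  - "2 MBax -> Bax2 @ 1.428571e-5"
  - "Bax2 -> 2 MBax @ 1.0e-3"
  - "Bax2 + Bcl2 -> Bax2_Bcl2 @ 1.428571e-5"
  - "Bax2_Bcl2 -> Bax2 + Bcl2 @ 1.0e-3"
  - "2 Bax2 -> Bax4 @ 1.428571e-5"
  - "Bax4 -> 2 Bax2 @ 1.0e-3"
  - "Bax4 + Bcl2 -> Bax4_Bcl2 @ 1.428571e-5"
  - "Bax4_Bcl2 -> Bax4 + Bcl2 @ 1.0e-3"
  - "Bax4 + M -> Bax4_M @ 1.428571e-5"
  - "Bax4_M -> Bax4 + M @ 1.0e-3"
  - "Bax4_M -> AM @ 1.0"
  # release of apoptogenic factors
  - "AM + mCytoC -> AM_mCytoC @ 2.857143e-5"
  - "AM_mCytoC -> AM + mCytoC @ 1.0e-3"
  - "AM_mCytoC -> AM + aCytoC @ 1.0e1"
  - "AM + mSmac -> AM_mSmac @ 2.857143e-5"
  - "AM_mSmac -> AM + mSmac @ 1.0e-3"
  - "AM_mSmac -> AM + aSmac @ 1.0e1"
  - "aCytoC -> cCytoC @ 1.0e-2"
  - "cCytoC -> aCytoC @ 1.0e-2"
  - "aSmac -> cSmac @ 1.0e-2"
  - "cSmac -> aSmac @ 1.0e-2"
  # apoptosome
  - "Apaf + cCytoC -> cCytoC_Apaf @ 5.0e-7"
  - "cCytoC_Apaf -> Apaf + cCytoC @ 1.0e-3"
  - "cCytoC_Apaf -> aApaf + cCytoC @ 1.0"
  - "aApaf + pC9 -> Apop @ 5.0e-8"
  - "Apop -> aApaf + pC9 @ 1.0e-3"
  - "Apop + pC3 -> Apop_pC3 @ 5.0e-9"
  - "Apop_pC3 -> Apop + pC3 @ 1.0e-3"
  - "Apop_pC3 -> Apop + C3 @ 1.0"
  - "Apop + XIAP -> Apop_XIAP @ 2.0e-6"
  - "Apop_XIAP -> Apop + XIAP @ 1.0e-3"
  - "cSmac + XIAP -> cSmac_XIAP @ 7.0e-6"
  - "cSmac_XIAP -> cSmac + XIAP @ 1.0e-3"
initial:
  R: 200
  flip: 100
  pC8: 20000
  BAR: 1000
  pC3: 10000
  pC6: 10000
  XIAP: 100000
  PARP: 1000000
  Bid: 40000
  Mcl1: 20000
  Bax: 100000
  Bcl2: 20000
  M: 500000
  mCytoC: 500000
  mSmac: 100000
  Apaf: 100000
  pC9: 100000
natives:
  - R
  - flip
  - pC8
  - BAR
  - pC3
  - pC6
  - XIAP
  - PARP
  - Bid
  - Mcl1
  - Bax
  - Bcl2
  - M
  - mCytoC
  - mSmac
  - Apaf
  - pC9
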