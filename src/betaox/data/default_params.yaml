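specificity:
  CPT1:
  - 16
  CACT:
  - 4
  - 6
  - 8
  - 10
  - 12
  - 14
  - 16
  CPT2:
  - 4
  - 6
  - 8
  - 10
  - 12
  - 14
  - 16
  VLCAD:
  - 12
  - 14
  - 16
  LCAD:
  - 8
  - 10
  - 12
  - 14
  - 16
  MCAD:
  - 6
  - 8
  - 10
  - 12
  SCAD:
  - 4
  - 6
  crotonase:
  - 4
  - 6
  - 8
  - 10
  - 12
  - 14
  - 16
  MSCHAD:
  - 4
  - 6
  - 8
  - 10
  - 12
  - 14
  - 16
  MCKAT:
  - 4
  - 6
  - 8
  - 10
  - 12
  - 14
  - 16
  MTP:
  - 8
  - 10
  - 12
  - 14
  - 16
volumes:
  V_MAT: 0.0005
totals:
  CoA_total: 1500.0
boundaries:
  palmitoylCoA_e: 25.0
  carnitine_e: 500.0
  CoASH_e: 0.5
  malonylCoA_e: 0.0
  NAD_m: 2812.5
  NADH_m: 187.5
initial:
  carnitine_m: 1000.0
parameters:
  CPT1:
    Vmax: 1.8
    Keq:
      16: 1.0
    Km:
      shared:
        CoASH_e: 40.0
        carnitine_e: 150.0
      16:
        acylcarnitine_C16_e: 60.0
        palmitoylCoA_e: 45.0
    Ki_malonylCoA: 10.0
  CACT:
    Vmax: 30.0
    Keq:
      4: 1.0
      6: 1.0
      8: 1.0
      10: 1.0
      12: 1.0
      14: 1.0
      16: 1.0
    Km:
      4:
        acylcarnitine_C4_e: 15.0
        acylcarnitine_C4_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
      6:
        acylcarnitine_C6_e: 15.0
        acylcarnitine_C6_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
      8:
        acylcarnitine_C8_e: 15.0
        acylcarnitine_C8_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
      10:
        acylcarnitine_C10_e: 15.0
        acylcarnitine_C10_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
      12:
        acylcarnitine_C12_e: 15.0
        acylcarnitine_C12_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
      14:
        acylcarnitine_C14_e: 15.0
        acylcarnitine_C14_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
      16:
        acylcarnitine_C16_e: 15.0
        acylcarnitine_C16_m: 15.0
        carnitine_e: 400.0
        carnitine_m: 400.0
  CPT2:
    Vmax: 20.0
    Keq:
      4: 1.0
      6: 1.0
      8: 1.0
      10: 1.0
      12: 1.0
      14: 1.0
      16: 1.0
    Km:
      4:
        CoASH_m: 30.0
        acylCoA_C4_m: 30.0
        acylcarnitine_C4_m: 25.0
        carnitine_m: 350.0
      6:
        CoASH_m: 30.0
        acylCoA_C6_m: 30.0
        acylcarnitine_C6_m: 25.0
        carnitine_m: 350.0
      8:
        CoASH_m: 30.0
        acylCoA_C8_m: 30.0
        acylcarnitine_C8_m: 25.0
        carnitine_m: 350.0
      10:
        CoASH_m: 30.0
        acylCoA_C10_m: 30.0
        acylcarnitine_C10_m: 25.0
        carnitine_m: 350.0
      12:
        CoASH_m: 30.0
        acylCoA_C12_m: 30.0
        acylcarnitine_C12_m: 25.0
        carnitine_m: 350.0
      14:
        CoASH_m: 30.0
        acylCoA_C14_m: 30.0
        acylcarnitine_C14_m: 25.0
        carnitine_m: 350.0
      16:
        CoASH_m: 30.0
        acylCoA_C16_m: 30.0
        acylcarnitine_C16_m: 25.0
        carnitine_m: 350.0
  VLCAD:
    Vmax: 2.2
    Keq:
      12: 3.0
      14: 3.0
      16: 3.0
    Km:
      12:
        acylCoA_C12_m: 4.0
        enoylCoA_C12_m: 8.0
      14:
        acylCoA_C14_m: 3.0
        enoylCoA_C14_m: 6.0
      16:
        acylCoA_C16_m: 2.0
        enoylCoA_C16_m: 4.0
  LCAD:
    Vmax: 1.8
    Keq:
      8: 3.0
      10: 3.0
      12: 3.0
      14: 3.0
      16: 3.0
    Km:
      8:
        acylCoA_C8_m: 12.0
        enoylCoA_C8_m: 24.0
      10:
        acylCoA_C10_m: 9.0
        enoylCoA_C10_m: 18.0
      12:
        acylCoA_C12_m: 7.0
        enoylCoA_C12_m: 14.0
      14:
        acylCoA_C14_m: 6.0
        enoylCoA_C14_m: 12.0
      16:
        acylCoA_C16_m: 8.0
        enoylCoA_C16_m: 16.0
  MCAD:
    Vmax: 2.5
    Keq:
      6: 3.0
      8: 3.0
      10: 3.0
      12: 3.0
    Km:
      6:
        acylCoA_C6_m: 6.0
        enoylCoA_C6_m: 12.0
      8:
        acylCoA_C8_m: 3.0
        enoylCoA_C8_m: 6.0
      10:
        acylCoA_C10_m: 4.0
        enoylCoA_C10_m: 8.0
      12:
        acylCoA_C12_m: 6.0
        enoylCoA_C12_m: 12.0
  SCAD:
    Vmax: 2.5
    Keq:
      4: 3.0
      6: 3.0
    Km:
      4:
        acylCoA_C4_m: 10.0
        enoylCoA_C4_m: 20.0
      6:
        acylCoA_C6_m: 18.0
        enoylCoA_C6_m: 36.0
  crotonase:
    Vmax: 14.0
    Keq:
      4: 2.892561983471074
      6: 2.892561983471074
      8: 2.892561983471074
      10: 2.892561983471074
      12: 2.892561983471074
      14: 2.892561983471074
      16: 2.892561983471074
    Km:
      4:
        enoylCoA_C4_m: 40.0
        hydroxyacylCoA_C4_m: 45.0
      6:
        enoylCoA_C6_m: 35.0
        hydroxyacylCoA_C6_m: 45.0
      8:
        enoylCoA_C8_m: 30.0
        hydroxyacylCoA_C8_m: 45.0
      10:
        enoylCoA_C10_m: 28.0
        hydroxyacylCoA_C10_m: 45.0
      12:
        enoylCoA_C12_m: 25.0
        hydroxyacylCoA_C12_m: 45.0
      14:
        enoylCoA_C14_m: 25.0
        hydroxyacylCoA_C14_m: 45.0
      16:
        enoylCoA_C16_m: 25.0
        hydroxyacylCoA_C16_m: 45.0
  MSCHAD:
    Vmax: 12.0
    Keq:
      4: 0.00022
      6: 0.00022
      8: 0.00022
      10: 0.00022
      12: 0.00022
      14: 0.00022
      16: 0.00022
    Km:
      4:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C4_m: 4.0
        ketoacylCoA_C4_m: 15.0
      6:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C6_m: 4.0
        ketoacylCoA_C6_m: 15.0
      8:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C8_m: 4.0
        ketoacylCoA_C8_m: 15.0
      10:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C10_m: 4.0
        ketoacylCoA_C10_m: 15.0
      12:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C12_m: 4.0
        ketoacylCoA_C12_m: 15.0
      14:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C14_m: 4.0
        ketoacylCoA_C14_m: 15.0
      16:
        NADH_m: 30.0
        NAD_m: 60.0
        hydroxyacylCoA_C16_m: 4.0
        ketoacylCoA_C16_m: 15.0
  MCKAT:
    Vmax: 8.0
    Keq:
      4: 1100.0
      6: 1100.0
      8: 1100.0
      10: 1100.0
      12: 1100.0
      14: 1100.0
      16: 1100.0
    Km:
      4:
        CoASH_m: 30.0
        ketoacylCoA_C4_m: 0.1
      6:
        CoASH_m: 30.0
        acylCoA_C4_m: 2.55
        ketoacylCoA_C6_m: 0.1
      8:
        CoASH_m: 30.0
        acylCoA_C6_m: 2.55
        ketoacylCoA_C8_m: 0.1
      10:
        CoASH_m: 30.0
        acylCoA_C8_m: 2.55
        ketoacylCoA_C10_m: 0.1
      12:
        CoASH_m: 30.0
        acylCoA_C10_m: 2.55
        ketoacylCoA_C12_m: 0.1
      14:
        CoASH_m: 30.0
        acylCoA_C12_m: 2.55
        ketoacylCoA_C14_m: 0.1
      16:
        CoASH_m: 30.0
        acylCoA_C14_m: 2.55
        ketoacylCoA_C16_m: 0.1
  MTP:
    Vmax: 10.0
    Keq:
      8: 0.7
      10: 0.7
      12: 0.7
      14: 0.7
      16: 0.7
    Km:
      shared:
        CoASH_m: 35.0
        NADH_m: 50.0
        NAD_m: 60.0
        acetylCoA_m: 40.0
      8:
        acylCoA_C6_m: 30.0
        enoylCoA_C8_m: 2.0
      10:
        acylCoA_C8_m: 30.0
        enoylCoA_C10_m: 2.0
      12:
        acylCoA_C10_m: 30.0
        enoylCoA_C12_m: 2.0
      14:
        acylCoA_C12_m: 30.0
        enoylCoA_C14_m: 2.0
      16:
        acylCoA_C14_m: 30.0
        enoylCoA_C16_m: 2.0
  acetylCoA_sink:
    K1acesink: 100.0
variant:
  competition: true
  malonyl_coa: 0.0
  nad_ratio: 15.0
  clamped_species: {}
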