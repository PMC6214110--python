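model,total_cost,cost_difference,rmsd,r2_training,r2_test,features
Hypo1,70.969,123.64,0.846,0.975,0.750,"HBA,HBD,HY,RA"
Hypo2,73.604,121.00,0.946,0.969,0.909,"HBA,HBD,HY,RA"
Hypo3,80.233,114.37,1.259,0.945,0.608,"HBA,HBA,HY,RA"
Hypo4,81.841,112.77,1.324,0.939,0.441,"HBA,HBD,HY,RA"
Hypo5,83.504,111.10,1.400,0.931,0.362,"HBA,HBD,HY,RA"
Hypo6,85.290,109.32,1.466,0.924,0.449,"HBA,HBD,HY,RA"
Hypo7,85.999,108.61,1.444,0.927,0.413,"HBA,HBD,HY,RA"
Hypo8,86.400,108.21,1.503,0.920,0.702,"HBD,HY,RA"
Hypo9,86.982,107.63,1.482,0.923,0.634,"HBA,HBD,HY,RA"
Hypo10,87.091,107.52,1.436,0.927,0.584,"HBA,HBD,HY,RA"
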