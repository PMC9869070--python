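name,cas,molar_mass,mce,pyruvate_per_mol,mrc,ebir,cdmp_printed,gwp20_o3_printed,gwp100_o3_printed,is_major
Acetic acid,64-19-7,60.05,1,1,13000,0.20,9200,5300,1100,true
Propionic acid,79-09-4,74.08,0,1,1600,0.34,,1100,220,false
Butyric acid,107-92-6,88.11,2,2,160,0.55,160,1800,360,false
Isobutyric acid,79-31-2,88.11,0,0,320,0.38,,250,50,false
Isovaleric acid,503-74-2,102.13,0,0,2.5,0.96,,4.9,0.98,false
Methanol,67-56-1,32.04,0,0,200,0.20,,0.82,0.16,false
Ethanol,64-17-5,46.07,1,1,5000,0.57,4800,5800,1200,true
1-Propanol,71-23-8,60.10,0,1,1000,0.79,,1600,320,false
2-Propanol,67-63-0,60.10,0,1,160,0.26,,85,17,false
2-Propenol,107-18-6,58.10,0,1,7.9,2.75,,44,8.9,false
2-Methyl-1-propanol,78-83-1,74.12,0,1,10,0.72,,15,3.0,false
1-Butanol,71-36-3,74.12,2,2,6.3,0.88,7.5,11,2.3,false
2-Butanol,78-92-2,74.12,2,2,100,0.50,120,100,21,false
3-Methyl-1-butanol,123-51-3,88.15,1,2,16,0.90,7.9,29,5.9,false
1-Hexanol,111-27-3,102.16,0,0,10,0.82,,17,3.4,false
2-Phenylethanol,60-12-8,122.17,1,1,10,1.07,3.6,22,4.4,false
Acetone,67-64-1,58.08,0,1,13,0.09,,2.4,0.48,false
2-Butanone,78-93-3,72.11,2,2,25,0.37,31,19,3.8,false
3-Hydroxy-2-butanone,513-86-0,88.11,1,2,1100,0.37,560,830,170,false
Methyl acetate,79-20-9,74.08,1,1,250,0.04,150,20,4.1,false
Ethyl acetate,141-78-6,88.11,2,2,130,0.24,130,64,13,false
Ethyl lactate,97-64-3,118.13,1,2,200,0.59,74,240,48,false
Propyl acetate,109-60-4,102.13,1,2,250,0.31,110,160,32,false
Propyl lactate,616-09-1,132.16,0,2,160,0.35,,110,23,false
Acetaldehyde,75-07-0,44.05,1,1,100,1.61,200,330,66,false
Propionaldehyde,123-38-6,58.08,0,1,13,1.71,,45,9.1,false
2-Methylpropanal,78-84-2,72.11,0,1,16,1.35,,44,8.9,false
Butyraldehyde,123-72-8,72.11,2,2,16,1.45,19,47,9.5,false
3-Methylbutanal,590-86-3,86.13,1,2,100,1.21,51,250,50,false
Valeraldehyde,110-62-3,86.13,2,2,100,1.26,100,260,52,false
Hexanal,66-25-1,100.17,0,0,100,1.07,,220,44,false
Heptanal,111-71-7,114.19,1,2,13,0.90,4.9,2400,480,false
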