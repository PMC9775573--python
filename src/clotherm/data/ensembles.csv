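code,composition,group,it,fcl,icl_si,icl_clo,ret_raw,ret,recl,im,im_cl,notes
AL,,,0.099,1.00,0.000,0.00,,,,,,Nude manikin (air layer insulation)
SK,,,0.131,1.03,0.040,0.26,11.5,8.0,,,,Manikin's textile skin (cotton); source of the air-layer evaporative resistance
C1,1;2;8;9;10;11;15,operational_uniform,0.187,1.19,0.104,0.67,22.3,18.7,12.0,0.61,0.52,
C1A,1;2;8;9;10;11;14;15,operational_uniform,0.236,1.24,0.157,1.01,35.2,31.5,25.0,0.45,0.37,
C1B,1;2;8;9;10;11;14A;15,operational_uniform,0.245,1.24,0.166,1.07,,,,,,The same as C1A but with softshell zip fully closed (printed composition lists item 14; normalized to 14A)
C2,1;2;8;9;10;12;15,operational_uniform,0.205,1.19,0.122,0.79,25.7,22.0,15.4,0.56,0.48,
C2A,1;2;8;9;10;12;14;15,operational_uniform,0.237,1.26,0.159,1.03,32.9,29.3,23.0,0.49,0.42,
C2B,1;2;8;9;10;12;14;15;16,operational_uniform,0.241,1.27,0.163,1.05,,,,,,
C2C,1;3;8;9;10;12;14;15;29,operational_uniform,0.255,1.29,0.179,1.15,,,,,,
C2D,1;3;6;8;9;10;12;15;30A,operational_uniform,0.273,1.32,0.198,1.28,45.5,41.8,35.7,0.40,0.33,
C2E,1;3;6;8;9;10;12;15;30B,operational_uniform,0.282,1.33,0.208,1.34,,,,,,
C2F,1;3;6;8;9;10;12;15;30,operational_uniform,0.300,1.34,0.226,1.46,,,,,,
C2G,1;3;6;8;9;10;12;15;16;30,operational_uniform,0.307,1.34,0.234,1.51,48.0,44.3,38.3,0.42,0.37,The same as C2F but with technical rescue gloves (item 16)
C3,1;2;8;9;10;13;15,operational_uniform,0.227,1.26,0.148,0.95,,,,,,
C3A,1;3;6;8;9;10;13;15;16,operational_uniform,0.234,1.27,0.156,1.01,,,,,,
C3B,1;3;6;8;9;10;13;14;15;16,operational_uniform,0.271,1.29,0.194,1.25,41.9,38.2,32.0,0.43,0.36,
C4,1;4;8;9;10;12;15;17;18;19;22;31,incident,0.477,1.68,0.418,2.69,85.3,81.4,76.7,0.35,0.33,"31 consisting of 26 (hollanddoek fixed to 25), 28 and facemask similar to 31A but fixed to helmet"
C5,1;4;8;9;10;12;15;17;24;26,incident,0.436,1.60,0.374,2.41,,,,,,26 as part of 25
C6,1;4;8;9;10;12;15;17;21;22;26,incident,0.456,1.58,0.393,2.54,74.4,70.6,65.6,0.39,0.36,26 as part of 25
C6A,1;4;8;9;10;12;15;17;21;22;31,incident,0.465,1.65,0.405,2.62,87.4,83.6,78.8,0.34,0.31,"31 consisting of 26 (hollanddoek fixed to 25), 28 and facemask similar to 31A but fixed to helmet"
C6B,1;4;7;8;9;10;12;15;17;21;22;25;28;31A,incident,0.476,1.66,0.417,2.69,,,,,,
C6C,1;4;8;9;10;12;15;17;21;23;31,incident,0.457,1.65,0.397,2.56,,,,,,"31 consisting of 26 (hollanddoek fixed to 25), 28 and facemask similar to 31A but fixed to helmet"
C7,1;4;8;9;10;12;15;17;18;19;22;26,incident,0.466,1.57,0.403,2.60,,,,,,26 hollanddoek fixed to 25
C8,1;4;8;9;10;12;15;17;18;22;26A,incident,0.425,1.52,0.361,2.33,76.4,72.6,67.4,0.36,0.32,26A hollanddoek front open fixed to 25
C9,1;4;8;9;10;15;16;18;22;27,incident,0.372,1.49,0.305,1.97,,,,,,
C9A,1;4;8;9;10;12;15;16;18;22;27,incident,0.390,1.49,0.324,2.09,63.2,59.4,54.0,0.40,0.36,
C9B,1;4;8;9;10;12;15;17;18;22;27,incident,0.407,1.49,0.341,2.20,,,,,,
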