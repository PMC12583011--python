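item,M1_0.3_1000|RFAS,M1_0.3_1000|ACO,M1_0.6_300|RFAS,M1_0.6_300|ACO,M2_0.3_500|RFAS,M2_0.3_500|ACO,M2_0.6_1000|RFAS,M2_0.6_1000|ACO,M3_0.6_1000|RFAS,M3_0.6_1000|ACO,M4_0.3_1000|RFAS,M4_0.3_1000|ACO,M5_0.6_500|RFAS,M5_0.6_500|ACO,M5_0.3_1000|RFAS,M5_0.3_1000|ACO,M6_0.3_500|RFAS,M6_0.3_500|ACO,M6_0.6_500|RFAS,M6_0.6_500|ACO
X1,100,88,89,85,100,55,100,49,100,42,100,5,21,33,0,13,68,62,100,74
X2,99,43,44,52,7,8,14,17,100,86,0,99,77,26,99,29,98,100,100,98
X3,100,54,99,69,33,65,81,74,100,81,100,99,83,39,99,50,98,68,100,70
X4,100,79,32,73,17,12,81,13,99,19,100,97,31,75,95,66,100,32,100,30
X5,100,91,95,92,100,72,100,75,100,72,98,100,42,34,82,47,100,79,100,65
X6,69,30,8,45,82,22,91,21,100,17,100,100,31,75,49,84,100,97,100,92
X7,100,82,99,72,44,79,96,82,100,59,100,98,52,59,92,73,100,49,100,12
X8,100,79,99,66,28,71,63,81,100,36,100,95,29,70,56,73,100,57,100,46
X9,100,86,98,79,99,64,100,54,100,32,100,100,21,73,83,62,70,37,100,59
X10,100,68,94,67,72,47,98,34,100,77,15,7,46,16,49,3,71,91,100,98
X11,44,28,27,37,87,30,25,29,100,33,1,99,26,32,97,15,100,59,100,71
X12,100,55,72,57,89,36,70,31,100,80,0,79,29,66,3,75,100,93,100,96
X13,99,41,31,35,99,74,96,60,100,64,30,72,4,4,93,2,90,90,100,97
X14,100,95,100,85,95,32,100,23,100,13,2,99,62,45,3,63,100,86,100,92
X15,100,57,100,44,63,59,100,48,97,100,0,51,16,48,97,30,8,93,57,95
X16,100,91,100,95,0,43,0,82,100,100,49,100,12,83,3,85,16,20,27,7
X17,100,84,100,82,88,77,89,84,100,89,100,89,50,67,3,74,1,92,56,99
X18,100,89,100,90,80,21,32,16,100,98,83,96,2,46,3,39,91,95,96,99
X19,100,94,100,98,98,85,86,76,100,66,71,69,15,78,3,76,100,79,100,71
X20,100,66,80,77,0,38,0,51,100,49,100,46,8,31,97,41,100,100,100,96
X21,100,93,77,95,98,43,100,45,100,64,,,73,36,3,48,98,85,98,64
X22,100,90,100,84,85,50,89,44,100,78,,,90,67,5,68,85,36,51,69
X23,100,41,95,37,38,25,82,28,65,38,,,75,30,9,18,54,25,100,35
X24,100,86,95,91,6,75,9,81,7,35,,,86,72,8,62,100,98,99,78
X25,100,45,97,50,40,11,98,14,10,31,,,94,14,9,14,98,99,100,98
X26,100,79,100,81,99,65,100,59,44,41,,,90,61,6,53,46,78,95,89
X27,100,62,96,59,31,50,44,43,,,,,94,62,8,72,,,,
X28,88,26,87,23,89,17,67,30,,,,,82,41,9,53,,,,
X29,100,79,84,84,96,83,58,83,,,,,90,68,2,67,,,,
X30,100,99,99,96,83,76,91,73,,,,,92,49,7,45,,,,
X31,96,57,87,73,46,19,0,9,,,,,83,69,97,74,,,,
X32,100,76,84,84,99,31,91,21,,,,,69,61,61,48,,,,
X33,100,68,96,62,14,57,46,78,,,,,4,30,1,69,,,,
X34,100,62,98,54,100,65,100,56,,,,,73,75,94,69,,,,
X35,78,62,48,62,100,42,100,66,,,,,71,52,3,20,,,,
X36,100,79,100,85,99,79,98,83,,,,,75,49,93,32,,,,
X37,100,92,100,93,100,43,100,31,,,,,2,27,1,63,,,,
X38,100,89,100,92,93,64,100,59,,,,,65,47,77,54,,,,
X39,96,28,41,14,86,32,100,30,,,,,81,29,97,17,,,,
X40,100,87,100,81,100,63,100,67,,,,,73,61,96,54,,,,
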