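<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="skills" description="habilidades en las que el paciente era bueno">
    <category role="trigger">
      <pattern>HABILIDADES</pattern>
      <template><random>
        <li>Me contaron que se te daba muy bien <get name="habilidad_especial"/>. ¿Es cierto?</li>
        <li>Todos tenemos un talento. ¿En qué actividad eras muy hábil?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ HABILIDADES</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>HABILIDADES _</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HABILIDADES _</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>HABILIDAD</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HABILIDAD</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>HABILIDAD _</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ HABILIDAD _</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>TALENTO</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ TALENTO</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>TALENTO _</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ TALENTO _</pattern>
      <template><srai>HABILIDADES</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué talento! ¿Quién te enseñó a <get name="habilidad_especial"/>?</li>
        <li>¿Qué es lo que más te gustaba de <get name="habilidad_especial"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Gracias por contarme. ¿Qué actividad se te daba muy bien?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Seguro tienes muchos talentos. ¿Me cuentas alguno?</li>
        <li>Las manos guardan memoria. ¿Qué te gustaba crear o hacer?</li>
      </random></template>
    </category>
  </topic>
</aiml>
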